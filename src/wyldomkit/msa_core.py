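"""Sequences, alignments, clustering and conservation.

This module is the substrate layer of the pipeline: protein records, multiple
alignments, pairwise identity under the shorter-sequence denominator used by
greedy identity clustering, a deterministic progressive aligner (k-mer UPGMA
guide tree, profile-profile merges with BLOSUM62 and affine gaps), alignment
trimming, subunit-pair concatenation, and per-column conservation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._tables import AA_INDEX, ALPHABET, AMINO_ACIDS, GAP, blosum62

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an id and optional taxon label."""

    id: str
    residues: str
    taxon_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered rows of equal-length strings."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        n = len(self.rows[0][1])
        if n < 1:
            raise ValueError("alignment must have at least one column")
        for rid, row in self.rows:
            if len(row) != n:
                raise ValueError(f"row {rid!r} has length {len(row)} != {n}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def ungapped(self, row_id: str) -> str:
        for rid, row in self.rows:
            if rid == row_id:
                return row.replace(GAP, "")
        raise KeyError(row_id)

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(rid, row.replace(GAP, "")) for rid, row in self.rows]

    def column(self, col: int) -> str:
        """1-based column access."""
        return "".join(row[col - 1] for _, row in self.rows)

    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "Alignment":
        """Treat equal-length records as an already-aligned block."""
        return cls([(r.id, r.residues) for r in records])

    def occupancy(self) -> np.ndarray:
        """Fraction of non-gap characters per column."""
        mat = np.array([list(row) for _, row in self.rows])
        return (mat != GAP).mean(axis=0)


@dataclass
class ClusterSet:
    """A partition of sequence ids with one representative per cluster."""

    clusters: list[list[str]]
    representatives: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> set[str]:
        return {m for c in self.clusters for m in c}


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    # overhangs are free: identity under the shorter-sequence denominator
    # should not force terminal gaps into the aligned core
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older biopython naming
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    a.mode = "global"
    return a


_PAIR_ALIGNER = _aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical aligned residue pairs over the shorter length.

    The pair is globally aligned (BLOSUM62, affine gaps, free end gaps) and
    identities are counted over aligned columns; 'X' never counts as a match.
    Symmetric in its arguments and 1.0 for identical sequences.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot compute identity of an empty sequence")
    if a.residues == b.residues and "X" not in a.residues:
        return 1.0
    aln = _PAIR_ALIGNER.align(a.residues, b.residues)[0]
    ident = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for x, y in zip(a.residues[s1:e1], b.residues[s2:e2]):
            if x == y and x != "X":
                ident += 1
    return ident / min(len(a), len(b))


def greedy_cluster(records: list[SequenceRecord], threshold: float) -> ClusterSet:
    """Greedy incremental identity clustering (CD-HIT-like semantics).

    Records are visited by descending length (ties by id); each joins the
    first cluster whose representative it matches at identity >= threshold,
    otherwise it founds a new cluster. The founder, being the longest member,
    is the representative.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[SequenceRecord] = []
    clusters: list[list[str]] = []
    for rec in order:
        for ci, rep in enumerate(reps):
            if pairwise_identity(rec, rep) >= threshold:
                clusters[ci].append(rec.id)
                break
        else:
            reps.append(rec)
            clusters.append([rec.id])
    return ClusterSet(clusters=clusters, representatives=[r.id for r in reps])


def concatenate_pairs(
    pairs: list[tuple[SequenceRecord, SequenceRecord]],
) -> list[SequenceRecord]:
    """Concatenate separately encoded subunit pairs into single records.

    Used to score naturally fused two-module proteins and separately encoded
    subunit pairs on the same coordinate system before alignment.
    """
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for first, second in pairs:
        if first.id == second.id:
            raise ValueError(f"pair members share id {first.id!r}")
        new_id = f"{first.id}|{second.id}"
        if new_id in seen:
            raise ValueError(f"duplicate concatenated id {new_id!r}")
        seen.add(new_id)
        out.append(SequenceRecord(new_id, first.residues + second.residues))
    return out


# --- progressive alignment -------------------------------------------------

def _kmer_distance(records: list[SequenceRecord], k: int = 3) -> np.ndarray:
    """Condensed k-tuple distance matrix for the guide tree."""
    kk = min(k, min(len(r) for r in records))
    counts = []
    for r in records:
        c: dict[str, int] = {}
        for i in range(len(r) - kk + 1):
            w = r.residues[i : i + kk]
            c[w] = c.get(w, 0) + 1
        counts.append(c)
    n = len(records)
    d = np.zeros(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = counts[i], counts[j]
            shared = sum(min(v, cj.get(w, 0)) for w, v in ci.items())
            denom = min(len(records[i]), len(records[j])) - kk + 1
            d[idx] = 1.0 - shared / max(denom, 1)
            idx += 1
    return d


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (n_cols, 20); gaps and X carry no mass."""
    n_cols = len(rows[0])
    f = np.zeros((n_cols, 20))
    for row in rows:
        for j, ch in enumerate(row):
            if ch in AA_INDEX:
                f[j, AA_INDEX[ch]] += 1.0
    return f / len(rows)


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap profile-profile alignment; returns gap-expanded row sets.

    DP ties prefer the diagonal, then the vertical (consume-A) move.
    """
    fa, fb = _profile(rows_a), _profile(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    s = fa @ blosum62() @ fb.T
    neg = -np.inf
    m = np.full((la + 1, lb + 1), neg)
    x = np.full((la + 1, lb + 1), neg)  # gap in B, consumes A (vertical)
    y = np.full((la + 1, lb + 1), neg)  # gap in A, consumes B (horizontal)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        x[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, lb + 1):
        y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, la + 1):
        diag = np.maximum.reduce([m[i - 1, :-1], x[i - 1, :-1], y[i - 1, :-1]])
        m[i, 1:] = s[i - 1, :] + diag
        x[i, 1:] = np.maximum(m[i - 1, 1:] + GAP_OPEN, x[i - 1, 1:] + GAP_EXTEND)
        # horizontal chain via running max: y[i,j] = max_{l<j} m[i,l]+open+(j-l-1)*ext
        base = np.maximum.accumulate(
            np.maximum(m[i, :-1], x[i, :-1]) + GAP_OPEN - np.arange(lb) * GAP_EXTEND
        )
        y[i, 1:] = base + np.arange(lb) * GAP_EXTEND
    # traceback
    ops: list[str] = []
    i, j = la, lb
    state = max(
        [("M", m[i, j]), ("X", x[i, j]), ("Y", y[i, j])], key=lambda t: t[1]
    )[0] if (i or j) else "M"
    while i > 0 or j > 0:
        if i == 0:
            ops.append("B")
            j -= 1
            continue
        if j == 0:
            ops.append("A")
            i -= 1
            continue
        if state == "M":
            ops.append("D")
            prev = [("M", m[i - 1, j - 1]), ("X", x[i - 1, j - 1]), ("Y", y[i - 1, j - 1])]
            state = max(prev, key=lambda t: t[1])[0]
            i -= 1
            j -= 1
        elif state == "X":
            ops.append("A")
            state = "M" if m[i - 1, j] + GAP_OPEN >= x[i - 1, j] + GAP_EXTEND else "X"
            i -= 1
        else:
            ops.append("B")
            if m[i, j - 1] + GAP_OPEN >= y[i, j - 1] + GAP_EXTEND:
                state = "M"
            elif x[i, j - 1] + GAP_OPEN >= y[i, j - 1] + GAP_EXTEND:
                state = "X"
            else:
                state = "Y"
            j -= 1
    ops.reverse()
    new_a = ["".join(r[_i] if op != "B" else GAP
                     for op, _i in _op_indices(ops, "A")) for r in rows_a]
    new_b = ["".join(r[_i] if op != "A" else GAP
                     for op, _i in _op_indices(ops, "B")) for r in rows_b]
    return new_a, new_b


def _op_indices(ops: list[str], side: str) -> list[tuple[str, int]]:
    """Pair each op with the source column index it consumes on one side."""
    out = []
    idx = 0
    consume = {"A": ("D", "A"), "B": ("D", "B")}[side]
    for op in ops:
        out.append((op, idx))
        if op in consume:
            idx += 1
    return out


def progressive_align(records: list[SequenceRecord]) -> Alignment:
    """Progressive multiple alignment with a UPGMA k-mer guide tree.

    Deterministic given input order: guide-tree ties resolve by scipy's stable
    linkage ordering and DP ties prefer diagonal then vertical moves.
    Ungapping row k always reproduces input record k.
    """
    if not records:
        raise ValueError("no records to align")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(records) == 1:
        return Alignment([(records[0].id, records[0].residues)])
    nodes: dict[int, tuple[list[str], list[str]]] = {
        i: ([r.id], [r.residues]) for i, r in enumerate(records)
    }
    if len(records) == 2:
        merge_plan = [(0, 1, 2)]
    else:
        z = hierarchy.linkage(_kmer_distance(records), method="average")
        merge_plan = [(int(a), int(b), len(records) + i) for i, (a, b, _, _) in enumerate(z)]
    for a, b, new in merge_plan:
        ids_a, rows_a = nodes.pop(a)
        ids_b, rows_b = nodes.pop(b)
        new_a, new_b = _merge_profiles(rows_a, rows_b)
        nodes[new] = (ids_a + ids_b, new_a + new_b)
    (_, (final_ids, final_rows)), = nodes.items()
    by_id = dict(zip(final_ids, final_rows))
    return Alignment([(rid, by_id[rid]) for rid in ids])


def trim_alignment(aln: Alignment, start_col: int, end_col: int) -> Alignment:
    """Extract a 1-based inclusive column window.

    Rows that become all-gap are dropped and all-gap columns inside the window
    are removed, so the result satisfies the alignment invariants.
    """
    if not (1 <= start_col <= end_col <= aln.n_columns):
        raise ValueError(
            f"column window {start_col}..{end_col} out of range 1..{aln.n_columns}"
        )
    windows = [(rid, row[start_col - 1 : end_col]) for rid, row in aln.rows]
    keep_cols = [
        j for j in range(end_col - start_col + 1)
        if any(row[j] != GAP for _, row in windows)
    ]
    rows = [
        (rid, "".join(row[j] for j in keep_cols))
        for rid, row in windows
        if any(c != GAP for c in row)
    ]
    if not rows:
        raise ValueError("trim window leaves no non-empty rows")
    return Alignment(rows)


def conservation_scores(
    aln: Alignment, variant: str = "entropy"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column conservation in [0, 1] plus a low-confidence flag array.

    The default variant is entropy-based with independent counts: per column
    the gap-excluding residue frequencies f_a give H = -sum f_a ln f_a and the
    score 1 - H/ln(20). The "sum_of_pairs" variant averages BLOSUM62 scores
    over residue pairs, min-max scaled to [0, 1]. Columns with > 50% gaps are
    flagged low-confidence; all-gap columns score NaN.
    """
    if aln.n_rows < 2:
        raise ValueError("conservation requires at least 2 rows")
    if variant not in ("entropy", "sum_of_pairs"):
        raise ValueError(f"unknown conservation variant {variant!r}")
    scores = np.empty(aln.n_columns)
    low_conf = np.zeros(aln.n_columns, dtype=bool)
    b62 = blosum62()
    smin, smax = b62.min(), b62.max()
    for c in range(1, aln.n_columns + 1):
        col = aln.column(c)
        residues = [ch for ch in col if ch in AA_INDEX]
        gap_frac = 1.0 - len(residues) / len(col)
        low_conf[c - 1] = gap_frac > 0.5
        if not residues:
            scores[c - 1] = np.nan
            continue
        if variant == "entropy":
            counts = np.bincount([AA_INDEX[ch] for ch in residues], minlength=20)
            f = counts / counts.sum()
            nz = f[f > 0]
            h = float(-(nz * np.log(nz)).sum())
            scores[c - 1] = 1.0 - h / np.log(20.0)
        else:
            if len(residues) == 1:
                scores[c - 1] = np.nan
                continue
            idx = np.array([AA_INDEX[ch] for ch in residues])
            pair = b62[np.ix_(idx, idx)]
            n = len(idx)
            mean = (pair.sum() - np.trace(pair)) / (n * (n - 1))
            scores[c - 1] = (mean - smin) / (smax - smin)
    return scores, low_conf


# --- I/O -------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment_fasta(path) -> Alignment:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment(rows)


def write_alignment_fasta(aln: Alignment, path) -> None:
    bio = [_BioSeqRecord(Seq(row), id=rid, description="") for rid, row in aln.rows]
    SeqIO.write(bio, str(path), "fasta")


def write_clusters_tsv(cs: ClusterSet, records: list[SequenceRecord], path) -> None:
    by_id = {r.id: r for r in records}
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tmember_id\tidentity\n")
        for ci, (members, rep) in enumerate(zip(cs.clusters, cs.representatives)):
            for m in members:
                ident = pairwise_identity(by_id[m], by_id[rep])
                fh.write(f"{ci}\t{rep}\t{m}\t{ident:.4f}\n")
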