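"""Clan-level domain-architecture classification of annotated proteins.

Proteins are scanned against a model library, same-clan overlapping hits are
resolved, ordered clan signatures are formed (tandem repeats preserved, so
natural fusion proteins stay distinguishable), and signatures are grouped
into classes with member counts, protein-length statistics and per-domain
boundary medians. Display filtering hides rare classes from figures while
the machine output always retains the full set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa_core import SequenceRecord
from .phmm_engine import DomainHit, ProfileHMM, SearchThresholds, scan

ClanMap = dict[str, str]

_BRUTE_FORCE_LIMIT = 12

DEFAULT_EVALUE_CUT = 0.01
DEFAULT_MIN_DISPLAY = 100
DEFAULT_LENGTH_THRESHOLD = 127


def read_clan_map(path) -> ClanMap:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["model"], df["clan"]))


def clan_of(model_name: str, clans: ClanMap | None) -> str:
    if clans is None:
        return model_name
    return clans.get(model_name, model_name)


def annotate_proteome(
    models: list[ProfileHMM],
    db: list[SequenceRecord],
    th: SearchThresholds | None = None,
) -> dict[str, list[DomainHit]]:
    """Scan every protein against the library; keep only included hits."""
    th = th or SearchThresholds.scan_defaults()
    out: dict[str, list[DomainHit]] = {}
    for seq in db:
        out[seq.id] = [h for h in scan(models, seq, th) if h.included]
    return out


def _overlap_conflict(a: DomainHit, b: DomainHit) -> bool:
    ov = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
    shorter = min(a.env_length, b.env_length)
    return ov > 0.5 * shorter


def resolve_overlaps(
    hits: list[DomainHit], clans: ClanMap | None = None
) -> list[DomainHit]:
    """Resolve same-clan envelope overlaps (> 50% of the shorter envelope).

    Within each conflict component the kept subset maximizes summed bit
    score (exact search on small components, best-first greedy on very large
    ones); ties prefer lower total i-E-value, then model names. Cross-clan
    overlaps are untouched. Output is sorted by envelope start.
    """
    by_clan: dict[str, list[DomainHit]] = {}
    for h in hits:
        key = clan_of(h.model_name, clans) if clans else h.clan
        by_clan.setdefault(key, []).append(h)
    kept: list[DomainHit] = []
    for _, group in sorted(by_clan.items()):
        n = len(group)
        group = sorted(group, key=lambda h: (h.env_start, h.env_end, h.model_name))
        adj = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if _overlap_conflict(group[i], group[j]):
                    adj[i][j] = adj[j][i] = True
        # connected components of the conflict graph
        comp = [-1] * n
        for i in range(n):
            if comp[i] >= 0:
                continue
            stack, comp[i] = [i], i
            while stack:
                u = stack.pop()
                for v in range(n):
                    if adj[u][v] and comp[v] < 0:
                        comp[v] = i
                        stack.append(v)
        for root in sorted(set(comp)):
            members = [i for i in range(n) if comp[i] == root]
            if len(members) == 1:
                kept.append(group[members[0]])
            elif len(members) <= _BRUTE_FORCE_LIMIT:
                kept.extend(group[i] for i in _best_subset(group, members, adj))
            else:
                kept.extend(group[i] for i in _greedy_subset(group, members, adj))
    kept.sort(key=lambda h: (h.env_start, h.env_end, h.model_name))
    return kept


def _best_subset(group, members, adj) -> list[int]:
    best = None
    for r in range(len(members), 0, -1):
        for sub in itertools.combinations(members, r):
            if any(adj[a][b] for a, b in itertools.combinations(sub, 2)):
                continue
            score = sum(group[i].bit_score for i in sub)
            e_tot = sum(group[i].i_evalue for i in sub)
            names = tuple(group[i].model_name for i in sub)
            key = (-score, e_tot, names)
            if best is None or key < best[0]:
                best = (key, list(sub))
    return best[1] if best else []


def _greedy_subset(group, members, adj) -> list[int]:
    order = sorted(
        members,
        key=lambda i: (group[i].i_evalue, -group[i].bit_score, group[i].model_name),
    )
    chosen: list[int] = []
    for i in order:
        if all(not adj[i][j] for j in chosen):
            chosen.append(i)
    return sorted(chosen)


def signature_of(
    hits: list[DomainHit], evalue_cut: float = DEFAULT_EVALUE_CUT
) -> tuple[str, ...]:
    """Ordered clan signature of resolved hits below the i-E-value cut.

    Repeated clans are kept as repeats, so tandem fusions remain
    distinguishable from single-module architectures. An empty tuple means
    the protein is unclassified.
    """
    passing = [h for h in hits if h.i_evalue < evalue_cut]
    passing.sort(key=lambda h: (h.env_start, h.env_end, h.model_name))
    return tuple(h.clan for h in passing)


@dataclass
class ArchitectureClass:
    """A clan-level architecture with its member statistics."""

    label: str
    signature: tuple[str, ...]
    member_ids: list[str]
    median_length: float
    length_sd: float
    median_domain_boundaries: list[tuple[float, float]]
    n_sequences: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences == 0:
            self.n_sequences = len(self.member_ids)
        if self.n_sequences < 1 or self.n_sequences != len(self.member_ids):
            raise ValueError("class must have n_sequences == |member_ids| >= 1")


def _label(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    label = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        label = letters[r] + label
    return label


def group_classes(
    annotations: dict[str, list[DomainHit]],
    lengths: dict[str, int],
    evalue_cut: float = DEFAULT_EVALUE_CUT,
) -> tuple[list[ArchitectureClass], list[str]]:
    """Group proteins by signature into labeled classes.

    Classes are sorted by descending member count (ties by signature) and
    labeled A, B, C, ... in that order; proteins with an empty signature are
    returned separately as the unclassified set, never merged into a class.
    """
    by_sig: dict[tuple[str, ...], list[str]] = {}
    unclassified: list[str] = []
    for seq_id in sorted(annotations):
        sig = signature_of(annotations[seq_id], evalue_cut)
        if not sig:
            unclassified.append(seq_id)
        else:
            by_sig.setdefault(sig, []).append(seq_id)
    ordered = sorted(by_sig.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    classes: list[ArchitectureClass] = []
    for idx, (sig, members) in enumerate(ordered):
        lens = np.array([lengths[m] for m in members], dtype=float)
        bounds = []
        for d in range(len(sig)):
            starts, ends = [], []
            for m in members:
                passing = sorted(
                    (h for h in annotations[m] if h.i_evalue < evalue_cut),
                    key=lambda h: (h.env_start, h.env_end, h.model_name),
                )
                starts.append(passing[d].env_start)
                ends.append(passing[d].env_end)
            bounds.append((float(np.median(starts)), float(np.median(ends))))
        sd = float(np.std(lens, ddof=1)) if len(lens) > 1 else 0.0
        classes.append(
            ArchitectureClass(
                label=_label(idx),
                signature=sig,
                member_ids=members,
                median_length=float(np.median(lens)),
                length_sd=sd,
                median_domain_boundaries=bounds,
            )
        )
    return classes, unclassified


def filter_display_classes(
    classes: list[ArchitectureClass], min_members: int = DEFAULT_MIN_DISPLAY
) -> list[ArchitectureClass]:
    """Display filter: classes with fewer members than the cut are hidden."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    return [c for c in classes if c.n_sequences >= min_members]


def composite_length_split(
    hits: list[DomainHit], threshold: int = DEFAULT_LENGTH_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Partition composite-model hits by envelope length at the threshold.

    Ties at the threshold go to the short side, consistent with the
    maturation stratification. Returns (long ids, short ids).
    """
    long_ids = [h.sequence_id for h in hits if h.env_length > threshold]
    short_ids = [h.sequence_id for h in hits if h.env_length <= threshold]
    return long_ids, short_ids


def domain_free_regions(
    seq: SequenceRecord, hits: list[DomainHit], min_len: int = 80
) -> list[tuple[int, int]]:
    """Regions of at least `min_len` residues with no included hit.

    Emitted for manual inspection rather than automatic reclassification.
    """
    covered = np.zeros(len(seq) + 2, dtype=bool)
    for h in hits:
        covered[h.env_start : h.env_end + 1] = True
    regions = []
    start = None
    for pos in range(1, len(seq) + 2):
        free = pos <= len(seq) and not covered[pos]
        if free and start is None:
            start = pos
        elif not free and start is not None:
            if pos - start >= min_len:
                regions.append((start, pos - 1))
            start = None
    return regions


# --- tabular output ---------------------------------------------------------

def write_architecture_tsv(
    annotations: dict[str, list[DomainHit]],
    lengths: dict[str, int],
    path,
    evalue_cut: float = DEFAULT_EVALUE_CUT,
) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tsignature\tlength\thits\n")
        for seq_id in sorted(annotations):
            sig = signature_of(annotations[seq_id], evalue_cut)
            hits = ";".join(
                f"{h.model_name}:{h.env_start}-{h.env_end}"
                for h in sorted(annotations[seq_id], key=lambda h: h.env_start)
            )
            fh.write(f"{seq_id}\t{','.join(sig) or '-'}\t{lengths[seq_id]}\t{hits}\n")


def write_class_summary_tsv(classes: list[ArchitectureClass], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "label\tsignature\tn_sequences\tmedian_length\tlength_sd\t"
            "median_boundaries\n"
        )
        for c in classes:
            bounds = ";".join(f"{s:.1f}-{e:.1f}" for s, e in c.median_domain_boundaries)
            fh.write(
                f"{c.label}\t{','.join(c.signature)}\t{c.n_sequences}\t"
                f"{c.median_length:.1f}\t{c.length_sd:.2f}\t{bounds}\n"
            )
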