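"""Iterative definition and maturation of new domain profile HMMs.

Implements the protocol used to carve a clean WYL-domain model (and its
companions: the C-terminal WCX extension and the two winged-HTH variants)
out of composite hits: length-stratified sampling around the 127-residue
split, automated seed curation, identity clustering of the seed, boundary
definition from short-hit C-termini, and rebuild-and-research iterations
gated by a bit-score gathering threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .msa_core import (
    Alignment,
    SequenceRecord,
    greedy_cluster,
    pairwise_identity,
    progressive_align,
    trim_alignment,
)
from .phmm_engine import (
    DomainHit,
    ProfileHMM,
    SearchThresholds,
    build_profile,
    calibrate,
    search,
)


class MaturationError(RuntimeError):
    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class MaturationConfig:
    """Protocol parameters; the defaults are the WYL-model settings.

    Presets: `hth()` (90% clustering, one iteration, gathering 30.0) and
    `wcx()` (no iteration, gathering 30.0).
    """

    length_threshold: int = 127
    n_per_stratum: int = 250
    cluster_identity: float = 0.70
    gathering_threshold: float = 27.0
    iterations: int = 3
    seed: int = 0
    curation_max_gap_fraction: float = 0.5
    calibration_n: int = 150
    calibration_length: int = 300

    def __post_init__(self) -> None:
        if self.length_threshold <= 0:
            raise ValueError("length_threshold must be > 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0.0 < self.cluster_identity <= 1.0):
            raise ValueError("cluster_identity must be in (0, 1]")

    @classmethod
    def hth(cls, **kw) -> "MaturationConfig":
        kw.setdefault("cluster_identity", 0.90)
        kw.setdefault("gathering_threshold", 30.0)
        kw.setdefault("iterations", 1)
        return cls(**kw)

    @classmethod
    def wcx(cls, **kw) -> "MaturationConfig":
        kw.setdefault("gathering_threshold", 30.0)
        kw.setdefault("iterations", 0)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "MaturationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class SeedAlignment:
    """A curated alignment with domain boundary columns and hit provenance."""

    alignment: Alignment
    domain_start_col: int
    domain_end_col: int
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.alignment.n_columns
        if not (1 <= self.domain_start_col <= self.domain_end_col <= n):
            raise ValueError("boundary columns outside alignment")
        if len(set(self.provenance)) != len(self.provenance):
            raise ValueError("duplicate provenance ids")


def stratified_sample(
    hits: list[DomainHit], cfg: MaturationConfig
) -> tuple[list[str], list[str]]:
    """Length-stratified sampling of hit sequence ids.

    The long stratum holds envelope lengths strictly above the threshold; a
    length exactly at the threshold goes to the short stratum. Sampling is
    without replacement, reproducible under the config seed; an empty stratum
    yields an empty list.
    """
    long_ids = sorted({h.sequence_id for h in hits if h.env_length > cfg.length_threshold})
    short_ids = sorted({h.sequence_id for h in hits if h.env_length <= cfg.length_threshold})
    rng = np.random.default_rng(cfg.seed)
    out = []
    for ids in (long_ids, short_ids):
        n = min(cfg.n_per_stratum, len(ids))
        if n == 0:
            out.append([])
            continue
        pick = rng.choice(len(ids), size=n, replace=False)
        out.append([ids[i] for i in sorted(pick)])
    return out[0], out[1]


def _conserved_block(aln: Alignment) -> np.ndarray:
    """Column indices (0-based) with >= 50% occupancy."""
    return np.flatnonzero(aln.occupancy() >= 0.5)


def curate_seed(aln: Alignment, cfg: MaturationConfig) -> Alignment:
    """Drop rows with defective domain regions (automated curation proxy).

    A row is discarded when its gap fraction inside the conserved block
    exceeds the configured maximum, or when it lacks at least one residue in
    each tercile of the block — which removes truncated instances missing
    the N- or C-terminal half.
    """
    block = _conserved_block(aln)
    if block.size == 0:
        raise MaturationError("alignment has no conserved block to curate against")
    terciles = np.array_split(block, 3)
    kept = []
    for rid, row in aln.rows:
        in_block = [row[j] for j in block]
        gap_frac = in_block.count("-") / len(in_block)
        if gap_frac > cfg.curation_max_gap_fraction:
            continue
        if any(
            t.size > 0 and all(row[j] == "-" for j in t) for t in terciles
        ):
            continue
        kept.append((rid, row))
    if not kept:
        raise MaturationError("curation dropped every row")
    out = Alignment(kept)
    keep_cols = [j + 1 for j in range(out.n_columns)
                 if any(row[j] != "-" for _, row in out.rows)]
    if len(keep_cols) != out.n_columns:
        out = trim_alignment(out, 1, out.n_columns)
    return out


def define_boundaries(
    aln: Alignment, short_hit_ends: list[int]
) -> tuple[int, int]:
    """Domain boundary columns from occupancy and short-hit C-termini.

    The N-terminal boundary is the first column with >= 50% occupancy (the
    composite model's own start); the C-terminal boundary is the floor-median
    of the mapped end columns of the short-stratum hits.
    """
    if not short_hit_ends:
        raise ValueError("short_hit_ends must be non-empty")
    occ = aln.occupancy()
    starts = np.flatnonzero(occ >= 0.5)
    if starts.size == 0:
        raise MaturationError("no column reaches 50% occupancy")
    start_col = int(starts[0]) + 1
    end_col = int(np.floor(np.median(short_hit_ends)))
    if start_col >= end_col:
        raise MaturationError(
            f"inverted boundaries: start {start_col} >= end {end_col}"
        )
    return start_col, end_col


def _derived_seed(base: int, salt: int) -> int:
    return (base * 2654435761 + salt) % (2**31)


def _build_from_seed(
    seed_aln: Alignment, cfg: MaturationConfig, salt: int, name: str, clan: str
) -> ProfileHMM:
    """Cluster seed rows, keep representatives, build and calibrate."""
    records = seed_aln.to_records()
    cs = greedy_cluster(records, cfg.cluster_identity)
    reps = set(cs.representatives)
    rows = [(rid, row) for rid, row in seed_aln.rows if rid in reps]
    sub = trim_alignment(Alignment(rows), 1, len(rows[0][1]))
    model = build_profile(sub, name=name, clan=clan)
    calibrate(
        model,
        n_random=cfg.calibration_n,
        length=cfg.calibration_length,
        seed=_derived_seed(cfg.seed, salt),
    )
    return model


def mature_hmm(
    db: list[SequenceRecord],
    initial_seed: SeedAlignment,
    cfg: MaturationConfig,
    name: str = "model",
    clan: str = "",
    report: list | None = None,
) -> ProfileHMM:
    """Iterative rebuild-and-research maturation of a profile HMM.

    Each iteration clusters the seed at the configured identity, builds and
    calibrates a model, searches the database keeping domains scoring above
    the gathering threshold, re-aligns their envelopes and trims to the
    >= 50%-occupancy span to form the next seed. With zero iterations the
    model comes straight from the initial seed. Deterministic under the seed.
    """
    seed_aln = trim_alignment(
        initial_seed.alignment,
        initial_seed.domain_start_col,
        initial_seed.domain_end_col,
    )
    for it in range(1, cfg.iterations + 1):
        model = _build_from_seed(seed_aln, cfg, it, name, clan)
        results = search(model, db, SearchThresholds.search_defaults())
        hits = [
            h
            for r in results
            for h in r.hits
            if h.bit_score > cfg.gathering_threshold
        ]
        if not hits:
            raise MaturationError(
                f"iteration {it}: no hits above gathering threshold "
                f"{cfg.gathering_threshold}",
                iteration=it,
            )
        by_id = {s.id: s for s in db}
        envs = [
            SequenceRecord(
                f"{h.sequence_id}/{h.env_start}-{h.env_end}",
                by_id[h.sequence_id].residues[h.env_start - 1 : h.env_end],
            )
            for h in hits
        ]
        aln = progressive_align(envs)
        block = _conserved_block(aln)
        if block.size == 0:
            raise MaturationError(f"iteration {it}: degenerate re-alignment",
                                  iteration=it)
        seed_aln = trim_alignment(aln, int(block[0]) + 1, int(block[-1]) + 1)
        if report is not None:
            report.append({
                "iteration": it,
                "n_hits": len(hits),
                "n_kept": seed_aln.n_rows,
                "start_col": int(block[0]) + 1,
                "end_col": int(block[-1]) + 1,
                "model_checksum": model_checksum(model),
            })
    final = _build_from_seed(seed_aln, cfg, 0, name, clan)
    final.gathering_threshold = cfg.gathering_threshold
    if report is not None:
        report.append({
            "iteration": cfg.iterations + 1,
            "n_hits": 0,
            "n_kept": seed_aln.n_rows,
            "start_col": 1,
            "end_col": seed_aln.n_columns,
            "model_checksum": model_checksum(final),
        })
    return final


def model_checksum(model: ProfileHMM) -> str:
    h = hashlib.md5()
    h.update(model.match_emissions.tobytes())
    h.update(model.tmm.tobytes())
    h.update(model.tmi.tobytes())
    h.update(model.tmd.tobytes())
    return h.hexdigest()


def write_maturation_report(report: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("iteration\tn_hits\tn_kept\tstart_col\tend_col\tmodel_checksum\n")
        for r in report:
            fh.write(
                f"{r['iteration']}\t{r['n_hits']}\t{r['n_kept']}\t"
                f"{r['start_col']}\t{r['end_col']}\t{r['model_checksum']}\n"
            )


def split_wing_groups(
    aln: Alignment,
    labels: dict[str, str] | None = None,
    wing_cols: tuple[int, int] | None = None,
) -> tuple[SeedAlignment, SeedAlignment]:
    """Split an HTH seed alignment into the two wing sub-types.

    With explicit labels (two values) the partition follows them. Without
    labels a complete-linkage clustering of pairwise identities over the
    wing-region columns is cut into two groups. Both groups must be
    non-empty.
    """
    n_cols = aln.n_columns
    lo, hi = wing_cols if wing_cols else (1, n_cols)
    wing = trim_alignment(aln, lo, hi)
    wing_rows = dict(wing.rows)
    if labels is not None:
        values = sorted(set(labels.values()))
        if len(values) != 2:
            raise ValueError("labels must define exactly two groups")
        groups = {
            v: [rid for rid, _ in aln.rows if labels.get(rid) == v] for v in values
        }
    else:
        recs = [
            SequenceRecord(rid, wing_rows[rid].replace("-", "") or "X")
            for rid, _ in aln.rows
            if rid in wing_rows
        ]
        n = len(recs)
        if n < 2:
            raise ValueError("need at least two rows to split")
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - pairwise_identity(recs[i], recs[j])
                dist[i, j] = dist[j, i] = d
        z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        assign = hierarchy.fcluster(z, t=2, criterion="maxclust")
        groups = {
            "1": [recs[i].id for i in range(n) if assign[i] == 1],
            "2": [recs[i].id for i in range(n) if assign[i] == 2],
        }
    g1, g2 = (sorted(v) for v in groups.values())
    if not g1 or not g2:
        raise MaturationError(
            "wing split produced an empty group; provide explicit labels"
        )
    out = []
    for ids in (g1, g2):
        keep = set(ids)
        sub = Alignment([(rid, row) for rid, row in aln.rows if rid in keep])
        sub = trim_alignment(sub, 1, sub.n_columns)
        out.append(SeedAlignment(sub, 1, sub.n_columns, provenance=list(ids)))
    return out[0], out[1]
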