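"""Taxonomic aggregation of classified proteins.

Given a flat lineage table (sequence -> species -> ranked lineage), computes
per-taxon unique-species counts, sequence counts and sequences-per-species
averages (the ring-plot metrics), applies the small-group display filter,
excludes non-bacterial sequences, and computes per-organism averages over a
species universe that includes zero-hit species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

RANKS = ["superkingdom", "phylum", "class", "order", "family", "genus"]
DEFAULT_MIN_FRACTION = 0.015


@dataclass
class TaxonSummary:
    taxon: str
    rank: str
    n_species: int
    n_sequences: int
    avg_per_species: float
    fraction_of_species: float


def read_taxonomy_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sequence_id", "species_id", *RANKS} - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    return df


def _check_total(seq_ids: Iterable[str], tax: pd.DataFrame) -> pd.DataFrame:
    ids = list(seq_ids)
    sub = tax[tax["sequence_id"].isin(set(ids))]
    missing = set(ids) - set(sub["sequence_id"])
    if missing:
        raise ValueError(
            f"sequences missing from taxonomy table: {sorted(missing)[:10]}"
        )
    return sub


def exclude_nonbacterial(
    seq_ids: Iterable[str], tax: pd.DataFrame
) -> tuple[list[str], dict[str, int]]:
    """Partition annotated sequences into bacterial and excluded sets.

    Returns the bacterial sequence ids and a per-superkingdom count of the
    excluded remainder.
    """
    sub = _check_total(seq_ids, tax)
    bacterial = sorted(sub.loc[sub["superkingdom"] == "Bacteria", "sequence_id"])
    excluded = (
        sub.loc[sub["superkingdom"] != "Bacteria"]
        .groupby("superkingdom")["sequence_id"]
        .count()
        .to_dict()
    )
    return bacterial, excluded


def summarize_taxa(
    seq_ids: Iterable[str],
    tax: pd.DataFrame,
    rank: str,
    class_filter: str | None = None,
    class_of: dict[str, str] | None = None,
) -> list[TaxonSummary]:
    """Per-taxon species and sequence aggregates at a given rank.

    With a class filter, only sequences assigned to that architecture class
    contribute; the species fraction denominator is the species total of the
    considered set. Sorted by descending unique-species count.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    ids = list(seq_ids)
    if class_filter is not None:
        if class_of is None:
            raise ValueError("class_filter requires class assignments")
        if class_filter not in set(class_of.values()):
            raise ValueError(f"unknown class label {class_filter!r}")
        ids = [i for i in ids if class_of.get(i) == class_filter]
    sub = _check_total(ids, tax)
    if sub.empty:
        return []
    total_species = sub["species_id"].nunique()
    grouped = sub.groupby(rank).agg(
        n_species=("species_id", "nunique"), n_sequences=("sequence_id", "count")
    )
    out = [
        TaxonSummary(
            taxon=str(taxon),
            rank=rank,
            n_species=int(r.n_species),
            n_sequences=int(r.n_sequences),
            avg_per_species=r.n_sequences / r.n_species,
            fraction_of_species=r.n_species / total_species,
        )
        for taxon, r in grouped.iterrows()
    ]
    out.sort(key=lambda s: (-s.n_species, s.taxon))
    return out


def per_organism_average(
    seq_ids: Iterable[str],
    tax: pd.DataFrame,
    rank: str,
    taxon_label: str,
    species_universe: pd.DataFrame | None,
) -> float:
    """Hits per organism, averaged over ALL species of the taxon.

    Unlike the ring metric (which divides by species that have hits), the
    denominator here is the number of distinct species of the taxon present
    in the whole proteome collection, including zero-hit species — which is
    why the species universe is a required input.
    """
    if species_universe is None:
        raise ValueError("species universe required for the per-organism denominator")
    if rank not in species_universe.columns:
        raise ValueError(f"species universe lacks a {rank!r} column")
    n_species = int(
        species_universe.loc[species_universe[rank] == taxon_label, "species_id"]
        .nunique()
    )
    if n_species == 0:
        raise ValueError(f"taxon {taxon_label!r} absent from species universe")
    sub = _check_total(seq_ids, tax)
    n_hits = int((sub[rank] == taxon_label).sum())
    return n_hits / n_species


def filter_small_groups(
    summaries: list[TaxonSummary], min_fraction: float = DEFAULT_MIN_FRACTION,
    by: str = "species",
) -> list[TaxonSummary]:
    """Display filter dropping taxa below a fraction of the total.

    Filters on the species fraction by default (the ring radian metric); the
    sequence-fraction alternative is available via `by="sequences"`.
    """
    if not (0.0 <= min_fraction < 1.0):
        raise ValueError("min_fraction must be in [0, 1)")
    if by == "species":
        return [s for s in summaries if s.fraction_of_species >= min_fraction]
    if by == "sequences":
        total = sum(s.n_sequences for s in summaries)
        return [s for s in summaries if s.n_sequences / total >= min_fraction]
    raise ValueError(f"unknown filter basis {by!r}")


def write_summaries_tsv(summaries: list[TaxonSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "taxon\trank\tn_species\tn_sequences\tavg_per_species\t"
            "fraction_of_species\n"
        )
        for s in summaries:
            fh.write(
                f"{s.taxon}\t{s.rank}\t{s.n_species}\t{s.n_sequences}\t"
                f"{s.avg_per_species:.4f}\t{s.fraction_of_species:.4f}\n"
            )
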