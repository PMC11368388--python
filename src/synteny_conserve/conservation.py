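"""Per-gene conservation and uniqueness over a genome set.

``build_uniqueness`` joins the best-hit summary onto the processed
feature table: one row per (gene, other genome) pair, so "is this gene
unique?" and "where does it match?" are single filters.

``compute_colour_table`` restricts the counting to a plotted selection
of n genomes and maps each gene's conservation fraction —
match_count_in_set / (n-1), so 0 means unique within the set and 1
means present in every displayed genome — through a colour palette.
A "positive match" is the existence of a best hit passing the e-value
screen; no additional identity floor is applied for counting (identity
floors affect only cross-link rendering).  Counting is directional
(query -> subject).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from synteny_conserve.palettes import PALETTES, colour_for_fraction

UNIQUENESS_COLUMNS = [
    "genome_id",
    "key",
    "gene_name",
    "product",
    "start",
    "end",
    "subject_genome",
    "subject_key",
    "has_match",
    "percent_identity",
    "total_match_count",
]

COLOUR_COLUMNS = [
    "genome_id",
    "key",
    "gene_name",
    "product",
    "start",
    "end",
    "match_count_in_set",
    "conservation_fraction",
    "colour",
]


@dataclass
class SequenceSelection:
    """Plotted genomes: top-to-bottom order plus per-genome orientation."""

    entries: list[tuple[str, str]]  # (genome_id, "forward"|"reverse")

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate genome in selection")
        for _, orient in self.entries:
            if orient not in ("forward", "reverse"):
                raise ValueError(f"orientation must be forward/reverse, got {orient}")

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def orientation(self, genome_id: str) -> str:
        for g, o in self.entries:
            if g == genome_id:
                return o
        raise KeyError(genome_id)

    def __len__(self) -> int:
        return len(self.entries)


def read_selection_csv(path: str | Path) -> SequenceSelection:
    """Read a selection CSV with header ``sequence,orientation``.

    Orientation is encoded as 1 = forward, 0 = reverse, one row per
    genome in top-to-bottom plot order.
    """
    entries: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sequence" not in reader.fieldnames:
            raise ValueError(f"{path}: expected header 'sequence,orientation'")
        for row in reader:
            orient = str(row.get("orientation", "1")).strip()
            entries.append(
                (row["sequence"].strip(), "forward" if orient != "0" else "reverse")
            )
    return SequenceSelection(entries)


def build_uniqueness(
    best_hits: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Cross every processed feature with every other genome, join hits.

    One row per (feature, other genome) over all processed genomes.
    ``total_match_count`` is the number of distinct subject genomes in
    which the gene has a best hit; genes with no hit anywhere appear
    with ``has_match`` false in every row.
    """
    genomes = sorted(features["genome_id"].unique())
    if not best_hits.empty:
        known = set(zip(features["genome_id"], features["key"]))
        for qg, qk in zip(best_hits["query_genome"], best_hits["query_key"]):
            if (qg, qk) not in known:
                raise ValueError(
                    f"best-hit table references unknown feature {qg}:{qk}; "
                    "tables are out of sync"
                )
    base = features[["genome_id", "key", "gene_name", "product", "start", "end"]]
    others = pd.DataFrame(
        [
            {"genome_id": g, "subject_genome": s}
            for g in genomes
            for s in genomes
            if s != g
        ]
    )
    grid = base.merge(others, on="genome_id", how="left")
    hit_cols = best_hits[
        ["query_genome", "query_key", "subject_genome", "subject_key", "percent_identity"]
    ] if not best_hits.empty else pd.DataFrame(
        columns=[
            "query_genome",
            "query_key",
            "subject_genome",
            "subject_key",
            "percent_identity",
        ]
    )
    merged = grid.merge(
        hit_cols,
        left_on=["genome_id", "key", "subject_genome"],
        right_on=["query_genome", "query_key", "subject_genome"],
        how="left",
    ).drop(columns=["query_genome", "query_key"])
    merged["has_match"] = merged["percent_identity"].notna()
    counts = (
        merged.groupby(["genome_id", "key"])["has_match"]
        .sum()
        .astype("int64")
        .rename("total_match_count")
    )
    merged = merged.merge(counts, on=["genome_id", "key"], how="left")
    merged = merged.sort_values(
        ["genome_id", "start", "key", "subject_genome"], kind="mergesort"
    ).reset_index(drop=True)
    return merged[UNIQUENESS_COLUMNS]


def compute_colour_table(
    uniq: pd.DataFrame,
    selection: SequenceSelection,
    palette: str | Sequence[str] = "conservation",
) -> pd.DataFrame:
    """Count matches within the plotted set and assign gene colours.

    The conservation fraction of a gene is its number of matched
    genomes inside the selection divided by n-1; the palette gradient
    maps 0 (unique, palette start) to 1 (strictly conserved, palette
    end) deterministically.
    """
    if len(selection) < 2:
        raise ValueError("selection needs at least 2 genomes")
    sel = selection.genome_ids
    present = set(uniq["genome_id"].unique())
    missing = [g for g in sel if g not in present]
    if missing:
        raise ValueError(f"selection genomes absent from uniqueness table: {missing}")
    stops = PALETTES[palette] if isinstance(palette, str) else list(palette)
    sub = uniq[uniq["genome_id"].isin(sel) & uniq["subject_genome"].isin(sel)]
    grouped = (
        sub.groupby(["genome_id", "key", "gene_name", "product", "start", "end"], dropna=False)[
            "has_match"
        ]
        .sum()
        .astype("int64")
        .rename("match_count_in_set")
        .reset_index()
    )
    n = len(sel)
    grouped["conservation_fraction"] = grouped["match_count_in_set"] / (n - 1)
    grouped["colour"] = [
        colour_for_fraction(f, stops) for f in grouped["conservation_fraction"]
    ]
    grouped = grouped.sort_values(
        ["genome_id", "start", "key"], kind="mergesort"
    ).reset_index(drop=True)
    return grouped[COLOUR_COLUMNS]


def query_unique_genes(colour: pd.DataFrame, genome_id: str) -> pd.DataFrame:
    """Genes of one genome with no match inside the plotted set.

    Returns key, gene name and product sorted by start coordinate —
    the "which genes are unique to my phage?" query.
    """
    if genome_id not in set(colour["genome_id"]):
        raise KeyError(f"genome {genome_id} not in colour table")
    sub = colour[(colour["genome_id"] == genome_id) & (colour["match_count_in_set"] == 0)]
    sub = sub.sort_values("start", kind="mergesort").reset_index(drop=True)
    return sub[["key", "gene_name", "product", "start", "end"]]


def query_gene_matches(
    uniq: pd.DataFrame, gene: str, genome_id: str
) -> pd.DataFrame:
    """All genomes in which a given gene has a match.

    ``gene`` is resolved first as an exact (case-sensitive) key, then
    as a case-insensitive gene name, within ``genome_id``.  Returns the
    matching subject genome, the corresponding subject key, and the
    percent identity.
    """
    sub = uniq[uniq["genome_id"] == genome_id]
    if sub.empty:
        raise KeyError(f"genome {genome_id} not in uniqueness table")
    hit = sub[sub["key"] == gene]
    if hit.empty:
        names = sub["gene_name"].fillna("")
        hit = sub[names.str.lower() == gene.lower()]
    if hit.empty:
        near = sorted(
            k
            for k in set(sub["key"]) | set(sub["gene_name"].dropna())
            if gene.lower() in str(k).lower() or str(k).lower() in gene.lower()
        )[:5]
        raise KeyError(
            f"gene {gene!r} not found in {genome_id}"
            + (f"; near misses: {near}" if near else "")
        )
    out = hit[hit["has_match"]][
        ["subject_genome", "subject_key", "percent_identity"]
    ]
    return out.sort_values("subject_genome", kind="mergesort").reset_index(drop=True)
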