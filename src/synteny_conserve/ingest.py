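"""GenBank ingest: parsing, completeness checks, and key resolution.

GenBank files describe a genome as a sequence plus a list of annotated
features.  This module parses those files into flat, columnar feature
tables and decides, per genome, which qualifier serves as the stable
gene identifier (the *key*) used by every downstream join and plot:

* genomes annotated with ``gene`` (+``CDS``) features keyed by
  ``locus_tag``;
* genomes annotated with ``CDS`` features only keyed by ``protein_id``.

Coordinates are converted once, at the parse boundary, from GenBank's
1-based inclusive convention to 0-based half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from Bio import SeqIO

HOMOLOGY_TYPES = ("gene", "CDS")

#: columns of the raw feature table (genbank_df)
FEATURE_COLUMNS = [
    "genome_id",
    "feature_type",
    "locus_tag",
    "gene_name",
    "protein_id",
    "product",
    "start",
    "end",
    "strand",
    "translation",
    "compound",
    "segments",
]


class GenbankParseError(ValueError):
    """Raised when a file cannot be read as a GenBank record."""


@dataclass
class FeatureRow:
    """One gene/CDS feature, 0-based half-open coordinates.

    ``segments`` holds the exact (start, end) exon intervals for
    compound (join) locations; for simple locations it is the single
    ``[(start, end)]`` pair.  ``start``/``end`` are always the outermost
    bounds, which is what plotting uses.
    """

    genome_id: str
    feature_type: str
    start: int
    end: int
    strand: Literal["+", "-"]
    locus_tag: Optional[str] = None
    gene_name: Optional[str] = None
    protein_id: Optional[str] = None
    product: Optional[str] = None
    translation: Optional[str] = None
    compound: bool = False
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [(self.start, self.end)]


@dataclass
class GenomeRecord:
    """A parsed genome: identifier, sequence and ordered feature list."""

    genome_id: str
    description: str
    sequence: str
    features: list[FeatureRow]
    source_path: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ValidationReport:
    """Outcome of the per-genome completeness checks.

    ``routing`` states how the genome's identifiers resolve:
    ``gene_and_cds`` (keys from locus_tag), ``cds_only`` (keys from
    protein_id) or ``rejected`` (a blocking check failed).
    """

    genome_id: str
    checks: list[tuple[str, str, str]]
    routing: Literal["gene_and_cds", "cds_only", "rejected"]

    @property
    def ok(self) -> bool:
        return self.routing != "rejected"

    def failed_checks(self) -> list[tuple[str, str, str]]:
        return [c for c in self.checks if c[1] == "fail"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "genome_id": self.genome_id,
                "checks": [
                    {"check": n, "status": s, "detail": d} for n, s, d in self.checks
                ],
                "routing": self.routing,
            },
            sort_keys=True,
        )


def _first(qualifiers: dict, name: str) -> Optional[str]:
    vals = qualifiers.get(name)
    if not vals:
        return None
    v = str(vals[0]).strip()
    return v or None


def parse_genbank(path: str | Path) -> GenomeRecord:
    """Parse one GenBank flat file into a :class:`GenomeRecord`.

    All ``gene`` and ``CDS`` features are captured; other feature types
    (tRNA, regulatory, ...) are retained too and filtered downstream.
    Compound (join) locations are collapsed to their outermost bounds
    and flagged, with the exact segments kept for sequence extraction.
    Features are returned sorted by ascending start.
    """
    path = Path(path)
    if not path.exists():
        raise GenbankParseError(f"GenBank file not found: {path}")
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise GenbankParseError(f"cannot parse GenBank file {path}: {exc}") from exc

    sequence = str(record.seq).upper()
    if not sequence or set(sequence) == {"N"} and len(sequence) == 0:
        raise GenbankParseError(f"record {record.id} in {path} has no sequence")
    if len(sequence) == 0:
        raise GenbankParseError(f"record {record.id} in {path} has no sequence")

    genome_id = record.id or record.name
    features: list[FeatureRow] = []
    for feat in record.features:
        if feat.type == "source":
            continue
        ftype = feat.type if feat.type in HOMOLOGY_TYPES else "other"
        loc = feat.location
        if loc is None:
            continue
        parts = sorted(
            ((int(p.start), int(p.end)) for p in loc.parts), key=lambda p: p[0]
        )
        start, end = int(loc.start), int(loc.end)
        strand = "-" if (loc.strand or 1) < 0 else "+"
        q = feat.qualifiers
        features.append(
            FeatureRow(
                genome_id=genome_id,
                feature_type=ftype,
                start=start,
                end=end,
                strand=strand,
                locus_tag=_first(q, "locus_tag"),
                gene_name=_first(q, "gene"),
                protein_id=_first(q, "protein_id"),
                product=_first(q, "product"),
                translation=_first(q, "translation"),
                compound=len(parts) > 1,
                segments=parts,
            )
        )
    features.sort(key=lambda f: (f.start, f.end, f.feature_type))
    for f in features:
        if not (0 <= f.start < f.end <= len(sequence)):
            raise GenbankParseError(
                f"feature [{f.start},{f.end}) outside genome {genome_id} "
                f"of length {len(sequence)} in {path}"
            )
    return GenomeRecord(
        genome_id=genome_id,
        description=record.description,
        sequence=sequence,
        features=features,
        source_path=str(path),
    )


def _resolved_key(feat: FeatureRow) -> Optional[str]:
    """Per-feature identifier fallback chain: locus_tag, protein_id, gene."""
    return feat.locus_tag or feat.protein_id or feat.gene_name


def validate_record(record: GenomeRecord) -> ValidationReport:
    """Run the completeness checks on one parsed genome.

    Never raises: failures are encoded in the report so one bad file
    does not abort a multi-genome run.
    """
    checks: list[tuple[str, str, str]] = []

    seq_ok = record.length > 0
    checks.append(
        (
            "nonzero_sequence",
            "pass" if seq_ok else "fail",
            f"{record.length} bp",
        )
    )

    coding = [f for f in record.features if f.feature_type in HOMOLOGY_TYPES]
    genes = [f for f in coding if f.feature_type == "gene"]
    cds = [f for f in coding if f.feature_type == "CDS"]
    checks.append(
        (
            "has_coding_features",
            "pass" if coding else "fail",
            f"{len(genes)} gene, {len(cds)} CDS",
        )
    )

    if genes:
        routing = "gene_and_cds"
        missing = [f for f in genes if _resolved_key(f) is None]
    elif cds:
        routing = "cds_only"
        missing = [f for f in cds if f.protein_id is None and _resolved_key(f) is None]
    else:
        routing = "rejected"
        missing = []
    checks.append(
        (
            "identifier_available",
            "pass" if (coding and not missing) else "fail",
            "all features carry an identifier"
            if not missing
            else "no identifier on "
            + ", ".join(f"[{f.start},{f.end})" for f in missing[:5]),
        )
    )

    # uniqueness is assessed on the merged per-locus keys (a locus that
    # appears as both gene and CDS with the same locus_tag is one locus,
    # not a duplicate)
    keyed = genes if genes else cds
    keys = [_resolved_key(f) for f in keyed if _resolved_key(f) is not None]
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    checks.append(
        (
            "identifier_unique",
            "pass" if not dupes else "fail",
            "unique" if not dupes else "duplicates: " + ", ".join(dupes[:10]),
        )
    )

    bad_keys = sorted({k for k in keys if "|" in k})
    checks.append(
        (
            "identifier_charset",
            "pass" if not bad_keys else "fail",
            "no '|' in identifiers"
            if not bad_keys
            else "'|' found in: " + ", ".join(bad_keys[:5]),
        )
    )

    if any(status == "fail" for _, status, _ in checks):
        routing = "rejected"
    return ValidationReport(genome_id=record.genome_id, checks=checks, routing=routing)


def _feature_to_dict(feat: FeatureRow) -> dict:
    d = {
        "genome_id": feat.genome_id,
        "feature_type": feat.feature_type,
        "locus_tag": feat.locus_tag,
        "gene_name": feat.gene_name,
        "protein_id": feat.protein_id,
        "product": feat.product,
        "start": feat.start,
        "end": feat.end,
        "strand": feat.strand,
        "translation": feat.translation,
        "compound": feat.compound,
        "segments": json.dumps(feat.segments),
    }
    return d


def build_feature_table(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Flatten all gene/CDS (and other) features into one table.

    One row per feature across all genomes; this is the raw
    ``genbank_df`` table.
    """
    if not records:
        raise ValueError("no genomes loaded")
    rows = [_feature_to_dict(f) for rec in records for f in rec.features]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    df["compound"] = df["compound"].astype(bool)
    return df


def resolve_keys(
    table: pd.DataFrame, reports: Iterable[ValidationReport]
) -> pd.DataFrame:
    """Resolve one keyed row per locus: the ``processed_genbank_df`` table.

    For ``gene_and_cds`` genomes the key is the locus_tag (falling back
    per-feature to protein_id, then gene name); gene and CDS rows that
    share a locus_tag are merged so that protein-level fields
    (protein_id, product, translation) ride along with the locus.  For
    ``cds_only`` genomes the key is the protein_id.  Only gene/CDS
    features participate; the result is unique on (genome_id, key).
    """
    reports = list(reports)
    by_id = {r.genome_id: r for r in reports}
    out_rows: list[dict] = []
    for genome_id, sub in table.groupby("genome_id", sort=True):
        report = by_id.get(genome_id)
        if report is None or not report.ok:
            raise ValueError(
                f"genome {genome_id} is rejected or has no validation report; "
                "drop it before key resolution"
            )
        coding = sub[sub["feature_type"].isin(HOMOLOGY_TYPES)]
        if report.routing == "cds_only":
            primary = coding[coding["feature_type"] == "CDS"]
            key_field = "protein_id"
        else:
            primary = coding[coding["feature_type"] == "gene"]
            key_field = "locus_tag"
        cds_rows = coding[coding["feature_type"] == "CDS"]
        cds_by_tag = {
            row["locus_tag"]: row
            for _, row in cds_rows.iterrows()
            if row["locus_tag"]
        }
        for _, row in primary.iterrows():
            key = row[key_field] or row["protein_id"] or row["gene_name"]
            if key_field == "protein_id":
                key = row["protein_id"] or row["locus_tag"] or row["gene_name"]
            if not key:
                raise ValueError(
                    f"feature [{row['start']},{row['end']}) of genome "
                    f"{genome_id} has no usable identifier"
                )
            merged = dict(row)
            if row["feature_type"] == "gene" and row["locus_tag"] in cds_by_tag:
                cds = cds_by_tag[row["locus_tag"]]
                for fld in ("protein_id", "product", "translation"):
                    if not merged.get(fld):
                        merged[fld] = cds[fld]
                # the CDS interval is the coding region used for
                # extraction/translation; gene and CDS intervals agree in
                # practice for phage annotations, the CDS one is canonical
                merged["start"], merged["end"] = cds["start"], cds["end"]
                merged["strand"] = cds["strand"]
                merged["segments"] = cds["segments"]
                merged["compound"] = cds["compound"]
            merged["key"] = key
            out_rows.append(merged)
    df = pd.DataFrame(out_rows, columns=FEATURE_COLUMNS + ["key"])
    dup = df.duplicated(subset=["genome_id", "key"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["genome_id", "key"]].drop_duplicates()
        raise ValueError(
            "duplicate (genome, key) pairs after resolution: "
            + "; ".join(f"{g}:{k}" for g, k in pairs.itertuples(index=False))
        )
    df = df.sort_values(["genome_id", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    return df


def load_genbank_dir(genbank_dir: str | Path) -> list[GenomeRecord]:
    """Parse every ``.gb``/``.gbk`` file in a directory, sorted by name."""
    genbank_dir = Path(genbank_dir)
    paths = sorted(
        p for p in genbank_dir.iterdir() if p.suffix.lower() in (".gb", ".gbk")
    )
    return [parse_genbank(p) for p in paths]
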