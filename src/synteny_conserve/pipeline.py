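"""The four pipeline jobs: download, validate, blast, plot.

Thin orchestration over the library modules: each job reads/writes the
workspace artifacts, appends a record to the run-metadata log and
returns what it produced.  Jobs enforce step ordering through artifact
presence (a missing upstream table names the job to run), and the plot
job never touches upstream tables.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Literal, Optional

from synteny_conserve import artifacts
from synteny_conserve.artifacts import Workspace
from synteny_conserve.conservation import build_uniqueness
from synteny_conserve.homology import (
    all_vs_all,
    extract_gene_sequences,
    summarize_best_hits,
    translate_genes,
)
from synteny_conserve.ingest import (
    GenbankParseError,
    ValidationReport,
    build_feature_table,
    parse_genbank,
    resolve_keys,
    validate_record,
)
from synteny_conserve.ncbi import DownloadRequest, Transport, _urllib_transport
from synteny_conserve.ncbi import fetch_genbank, search_accessions

logger = logging.getLogger(__name__)


def download_job(
    data_dir: str | Path,
    request: DownloadRequest,
    transport: Transport = _urllib_transport,
    force: bool = False,
) -> list[Path]:
    ws = Workspace(data_dir)
    started = time.time()
    request.output_dir = ws.genbank_dir
    ids = search_accessions(request, transport)
    files = fetch_genbank(ids, request, transport, force=force) if ids else []
    ws.log_step(
        "download",
        "ok",
        artifacts=[str(p) for p in files],
        detail={"query": request.search_key, "n_ids": len(ids)},
        started=started,
    )
    return files


def validate_job(
    data_dir: str | Path, genbank_dir: Optional[str | Path] = None
) -> dict:
    """Parse + validate every GenBank file; write the feature tables.

    Rejected genomes are dropped with a warning (their reports are
    logged), and an unparseable file becomes a rejected report rather
    than aborting the run; the job fails only if no genome at all is
    accepted.
    """
    ws = Workspace(data_dir)
    started = time.time()
    gb_dir = Path(genbank_dir or ws.genbank_dir)
    paths = sorted(
        p for p in gb_dir.iterdir() if p.suffix.lower() in (".gb", ".gbk")
    ) if gb_dir.is_dir() else []
    if not paths:
        raise FileNotFoundError(f"no genomes loaded: no .gb/.gbk files in {gb_dir}")
    records = []
    reports: list[ValidationReport] = []
    for p in paths:
        try:
            rec = parse_genbank(p)
        except GenbankParseError as exc:
            logger.warning("skipping unparseable file %s: %s", p, exc)
            reports.append(
                ValidationReport(
                    genome_id=p.name,
                    checks=[("parseable", "fail", str(exc))],
                    routing="rejected",
                )
            )
            continue
        records.append(rec)
        reports.append(validate_record(rec))
    accepted = [
        r for r in records
        if next(rep for rep in reports if rep.genome_id == r.genome_id).ok
    ]
    for rep in reports:
        if not rep.ok:
            logger.warning(
                "genome %s rejected: %s",
                rep.genome_id,
                "; ".join(f"{n}: {d}" for n, s, d in rep.failed_checks()),
            )
    if not accepted:
        raise ValueError("no genomes loaded: every genome failed validation")
    table = build_feature_table(records)
    processed = resolve_keys(
        table[table["genome_id"].isin([r.genome_id for r in accepted])],
        [rep for rep in reports if rep.ok],
    )
    p1 = ws.write_table(table, artifacts.GENBANK_DF)
    p2 = ws.write_table(processed, artifacts.PROCESSED_DF)
    ws.log_step(
        "validate",
        "ok",
        artifacts=[str(p1), str(p2)],
        detail={
            "n_genomes": len(records),
            "n_accepted": len(accepted),
            "reports": [rep.to_json() for rep in reports],
        },
        started=started,
    )
    return {
        "records": records,
        "reports": reports,
        "feature_table": table,
        "processed": processed,
    }


def blast_job(
    data_dir: str | Path,
    mode: Literal["blastn", "blastp"] = "blastn",
    engine: Literal["builtin", "external"] = "builtin",
    evalue_threshold: float = 1e-3,
    genbank_dir: Optional[str | Path] = None,
) -> dict:
    """Extract (or translate) gene sequences, search, summarise, join."""
    ws = Workspace(data_dir)
    started = time.time()
    processed = ws.read_table(artifacts.PROCESSED_DF, step_hint="validate")
    gb_dir = Path(genbank_dir or ws.genbank_dir)
    needed = set(processed["genome_id"].unique())
    records = []
    for p in sorted(gb_dir.iterdir()):
        if p.suffix.lower() not in (".gb", ".gbk"):
            continue
        try:
            rec = parse_genbank(p)
        except GenbankParseError:
            continue  # already reported as rejected by the validate step
        if rec.genome_id in needed:
            records.append(rec)
    genes = extract_gene_sequences(processed, records)
    if mode == "blastp":
        genes = translate_genes(genes)
        if not genes:
            raise ValueError(
                "no translatable genes available for blastp; "
                "check CDS annotations or run blastn instead"
            )
    hits = all_vs_all(genes, mode=mode, engine=engine,
                      evalue_threshold=evalue_threshold)
    summary = summarize_best_hits(hits)
    uniqueness = build_uniqueness(summary, processed)
    p1 = ws.write_table(summary, artifacts.SUMMARY_FOR_MODE[mode])
    p2 = ws.write_table(uniqueness, artifacts.UNIQUENESS_FOR_MODE[mode])
    ws.log_step(
        mode,
        "ok",
        artifacts=[str(p1), str(p2)],
        detail={"engine": engine, "n_genes": len(genes), "n_hits": len(hits)},
        started=started,
    )
    return {"summary": summary, "uniqueness": uniqueness}
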