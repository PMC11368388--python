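"""Workspace layout and run-metadata logging.

A pipeline run lives in one data directory:

    data_dir/
      genbank/                  input GenBank files (.gb/.gbk)
      tables/                   parquet artifacts
      plots/                    rendered diagrams + their colour tables
      run_metadata.jsonl        append-only per-step log

All intermediate and queryable tables are Apache Parquet.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

GENBANK_DF = "genbank_df.parquet"
PROCESSED_DF = "processed_genbank_df.parquet"
BLASTN_SUMMARY = "blastn_summary.parquet"
BLASTP_SUMMARY = "blastp_summary.parquet"
GENE_UNIQUENESS = "gene_uniqueness.parquet"
PROTEIN_UNIQUENESS = "protein_uniqueness.parquet"
COLOUR_TABLE = "colour_table.parquet"

SUMMARY_FOR_MODE = {"blastn": BLASTN_SUMMARY, "blastp": BLASTP_SUMMARY}
UNIQUENESS_FOR_MODE = {"blastn": GENE_UNIQUENESS, "blastp": PROTEIN_UNIQUENESS}


class Workspace:
    """Path arithmetic for one run's data directory."""

    def __init__(self, data_dir: str | Path):
        self.data_dir = Path(data_dir)

    @property
    def genbank_dir(self) -> Path:
        return self.data_dir / "genbank"

    @property
    def tables_dir(self) -> Path:
        return self.data_dir / "tables"

    @property
    def plots_dir(self) -> Path:
        return self.data_dir / "plots"

    @property
    def metadata_log(self) -> Path:
        return self.data_dir / "run_metadata.jsonl"

    def table_path(self, name: str) -> Path:
        return self.tables_dir / name

    def write_table(self, df: pd.DataFrame, name: str) -> Path:
        self.tables_dir.mkdir(parents=True, exist_ok=True)
        path = self.table_path(name)
        df.to_parquet(path, index=False)
        return path

    def read_table(self, name: str, step_hint: str = "") -> pd.DataFrame:
        path = self.table_path(name)
        if not path.exists():
            hint = f"; run `{step_hint}` first" if step_hint else ""
            raise FileNotFoundError(f"missing artifact {path}{hint}")
        return pd.read_parquet(path)

    def log_step(
        self,
        step: str,
        status: str,
        artifacts: list[str] | None = None,
        detail: dict | None = None,
        started: float | None = None,
    ) -> None:
        """Append one step record to the JSONL run-metadata log."""
        self.data_dir.mkdir(parents=True, exist_ok=True)
        rec = {
            "step": step,
            "status": status,
            "started": started,
            "finished": time.time(),
            "artifacts": artifacts or [],
        }
        if detail:
            rec["detail"] = detail
        with open(self.metadata_log, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    def read_metadata(self) -> list[dict]:
        if not self.metadata_log.exists():
            return []
        return [
            json.loads(line)
            for line in self.metadata_log.read_text().splitlines()
            if line.strip()
        ]
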