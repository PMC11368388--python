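"""Run configuration: YAML file with environment-variable interpolation.

``${VAR}`` inside string values is replaced from the environment so
secrets (e.g. the NCBI API key) never need to live in the file.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from synteny_conserve.ncbi import DownloadRequest
from synteny_conserve.plot import PlotConfig

_ENV_RE = re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}")


def _interpolate(value: Any) -> Any:
    if isinstance(value, str):
        return _ENV_RE.sub(lambda m: os.environ.get(m.group(1), ""), value)
    if isinstance(value, dict):
        return {k: _interpolate(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_interpolate(v) for v in value]
    return value


@dataclass
class RunConfig:
    data_dir: Path = Path("data")
    genbank_dir: Optional[Path] = None  # defaults to data_dir/genbank
    run_blastn: bool = True
    run_blastp: bool = False
    evalue_threshold: float = 1e-3
    engine: str = "builtin"  # builtin | external
    download: Optional[DownloadRequest] = None
    plot: PlotConfig = field(default_factory=PlotConfig)

    def __post_init__(self) -> None:
        if self.engine not in ("builtin", "external"):
            raise ValueError(f"unknown engine {self.engine!r}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw = _interpolate(raw)
    download = None
    if "download" in raw:
        d = raw["download"]
        download = DownloadRequest(
            search_key=d.get("search_key", ""),
            email=d.get("email", ""),
            api_key=d.get("api_key") or None,
            max_records=int(d.get("max_records", 100)),
        )
    plot_kwargs = dict(raw.get("plot", {}))
    if "output_formats" in plot_kwargs:
        plot_kwargs["output_formats"] = tuple(plot_kwargs["output_formats"])
    plot = PlotConfig(**plot_kwargs)
    return RunConfig(
        data_dir=Path(raw.get("data_dir", "data")),
        genbank_dir=Path(raw["genbank_dir"]) if raw.get("genbank_dir") else None,
        run_blastn=bool(raw.get("run_blastn", True)),
        run_blastp=bool(raw.get("run_blastp", False)),
        evalue_threshold=float(raw.get("evalue_threshold", 1e-3)),
        engine=str(raw.get("engine", "builtin")),
        download=download,
        plot=plot,
    )
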