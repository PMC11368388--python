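"""Fetch GenBank records from the NCBI nucleotide database via Entrez.

A thin eutils client (esearch + efetch) with an injectable transport:
production use goes over HTTPS with urllib, tests inject a callable
serving canned responses.  NCBI requires a contact email; an API key
raises the polite request rate from 3/s to 10/s and can come from the
``NCBI_API_KEY`` environment variable.
"""

from __future__ import annotations

import logging
import os
import re
import time
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

logger = logging.getLogger(__name__)

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
API_KEY_ENV = "NCBI_API_KEY"

#: transport signature: (endpoint url, query params) -> response body text
Transport = Callable[[str, dict], str]

_EMAIL_RE = re.compile(r"^[^@\s]+@[^@\s]+\.[^@\s]+$")


@dataclass
class DownloadRequest:
    search_key: str
    email: str
    api_key: Optional[str] = None
    max_records: int = 100
    output_dir: str | Path = "genbank"

    def __post_init__(self) -> None:
        if not self.search_key.strip():
            raise ValueError("search_key must be non-empty")
        if not _EMAIL_RE.match(self.email or ""):
            raise ValueError(
                f"a valid contact email is required for NCBI Entrez access, "
                f"got {self.email!r}"
            )
        if self.max_records <= 0:
            raise ValueError("max_records must be positive")
        if self.api_key is None:
            self.api_key = os.environ.get(API_KEY_ENV) or None

    @property
    def delay(self) -> float:
        """Seconds between requests per NCBI policy."""
        return 0.11 if self.api_key else 0.34


def _urllib_transport(url: str, params: dict) -> str:
    data = urllib.parse.urlencode(params).encode()
    req = urllib.request.Request(url, data=data)
    with urllib.request.urlopen(req, timeout=60) as resp:
        return resp.read().decode()


def _request_with_retry(
    transport: Transport, url: str, params: dict, attempts: int = 3
) -> str:
    delay = 1.0
    for attempt in range(attempts):
        try:
            return transport(url, params)
        except Exception as exc:  # noqa: BLE001 - transport-defined failures
            if attempt == attempts - 1:
                raise RuntimeError(f"NCBI request failed after {attempts} attempts: {exc}") from exc
            logger.warning("NCBI request failed (%s); retrying in %.0fs", exc, delay)
            time.sleep(delay)
            delay *= 2
    raise AssertionError("unreachable")


def _common_params(req: DownloadRequest) -> dict:
    params = {"email": req.email, "tool": "synteny-conserve"}
    if req.api_key:
        params["api_key"] = req.api_key
    return params


def search_accessions(
    req: DownloadRequest, transport: Transport = _urllib_transport
) -> list[str]:
    """Run an Entrez esearch and return matching nucleotide accessions.

    Results come back in NCBI return order, capped at
    ``req.max_records``; an empty result is a warning, not an error.
    """
    params = {
        **_common_params(req),
        "db": "nucleotide",
        "term": req.search_key,
        "retmax": str(req.max_records),
        "idtype": "acc",
    }
    body = _request_with_retry(transport, f"{EUTILS_BASE}/esearch.fcgi", params)
    root = ET.fromstring(body)
    ids = [el.text for el in root.findall(".//IdList/Id") if el.text]
    if not ids:
        logger.warning("Entrez search %r returned no records", req.search_key)
    return ids[: req.max_records]


def fetch_genbank(
    ids: Sequence[str],
    req: DownloadRequest,
    transport: Transport = _urllib_transport,
    force: bool = False,
) -> list[Path]:
    """Fetch each accession as a GenBank flat file into ``req.output_dir``.

    Files are named ``<accession>.gb``; existing files are skipped
    unless ``force``, making repeated downloads idempotent.  Per-id
    failures are logged and skipped; if every fetch fails, an error is
    raised.
    """
    if not ids:
        raise ValueError("no accession ids to fetch")
    out_dir = Path(req.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    failures: list[str] = []
    for acc in ids:
        path = out_dir / f"{acc}.gb"
        if path.exists() and not force:
            logger.info("skipping %s (already downloaded)", acc)
            written.append(path)
            continue
        params = {
            **_common_params(req),
            "db": "nucleotide",
            "id": acc,
            "rettype": "gb",
            "retmode": "text",
        }
        try:
            body = _request_with_retry(transport, f"{EUTILS_BASE}/efetch.fcgi", params)
        except RuntimeError as exc:
            logger.error("fetch of %s failed: %s", acc, exc)
            failures.append(acc)
            continue
        if not body.startswith("LOCUS"):
            logger.error("fetch of %s returned non-GenBank payload", acc)
            failures.append(acc)
            continue
        path.write_text(body)
        written.append(path)
        time.sleep(req.delay)
    if failures and not written:
        raise RuntimeError(f"all fetches failed: {failures}")
    return written
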