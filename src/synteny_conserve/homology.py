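"""All-vs-all gene-level homology search and best-hit reduction.

The unit of comparison is the gene, not the genome: each gene's
nucleotide (or translated protein) sequence is searched against the
gene/protein set of every *other* genome, and for each (query gene,
subject genome) pair only the single best-scoring match is retained.

Two engines implement the search contract:

* ``external`` — BLAST+ (``makeblastdb`` + ``blastn``/``blastp`` with
  tabular output), the production engine;
* ``builtin`` — global Needleman–Wunsch alignment through Biopython's
  :class:`Bio.Align.PairwiseAligner` with BLAST-like scoring, so the
  pipeline runs without external binaries.  Its bitscore surrogate is
  the raw alignment score and its e-value surrogate comes from a
  Karlin–Altschul approximation with fixed constants.

Percent identity follows the BLAST convention: identical columns
divided by alignment length (gaps included), times 100.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from synteny_conserve.ingest import GenomeRecord

BEST_HIT_COLUMNS = [
    "query_genome",
    "query_key",
    "subject_genome",
    "subject_key",
    "percent_identity",
    "alignment_length",
    "bitscore",
    "evalue",
]

#: Karlin–Altschul surrogate constants for the builtin engine's e-value,
#: (lambda, K); values in the range BLAST reports for gapped searches.
_KA_PARAMS = {"nucleotide": (0.625, 0.41), "protein": (0.267, 0.041)}

DEFAULT_EVALUE = 1e-3


@dataclass
class GeneSequence:
    """One gene's sequence, read 5'->3' in gene orientation."""

    genome_id: str
    key: str
    seq: str
    kind: Literal["nucleotide", "protein"]
    provided_translation: Optional[str] = None
    internal_stop: bool = False


@dataclass
class RawHit:
    query_genome: str
    query_key: str
    subject_genome: str
    subject_key: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    evalue: float


def extract_gene_sequences(
    features: pd.DataFrame, records: Sequence[GenomeRecord]
) -> list[GeneSequence]:
    """Slice each processed feature's nucleotide sequence from its genome.

    Compound locations are stitched from their exact segments;
    minus-strand features are reverse-complemented so every returned
    sequence reads 5'->3' in gene orientation.
    """
    seqs = {r.genome_id: r.sequence for r in records}
    out: list[GeneSequence] = []
    for row in features.itertuples(index=False):
        genome_seq = seqs.get(row.genome_id)
        if genome_seq is None:
            raise ValueError(f"no genome record for {row.genome_id}")
        segments = json.loads(row.segments) if isinstance(row.segments, str) else [
            (row.start, row.end)
        ]
        for s, e in segments:
            if not (0 <= s < e <= len(genome_seq)):
                raise ValueError(
                    f"feature {row.key} of {row.genome_id} outside sequence: "
                    f"[{s},{e}) vs length {len(genome_seq)}"
                )
        seq = "".join(genome_seq[s:e] for s, e in segments)
        if row.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append(
            GeneSequence(
                genome_id=row.genome_id,
                key=row.key,
                seq=seq,
                kind="nucleotide",
                provided_translation=row.translation or None,
            )
        )
    return out


def translate_genes(genes: Sequence[GeneSequence]) -> list[GeneSequence]:
    """Translate nucleotide gene sequences with the bacterial code (table 11).

    A ``translation`` qualifier carried over from the GenBank file takes
    precedence over recomputation.  Sequences whose length is not a
    multiple of three are truncated to the codon boundary; an internal
    stop truncates the protein there and flags it.
    """
    out: list[GeneSequence] = []
    for g in genes:
        if g.kind != "nucleotide":
            raise ValueError(f"translate_genes expects nucleotide input, got {g.kind}")
        if g.provided_translation:
            prot, internal = g.provided_translation, False
        else:
            nt = g.seq[: len(g.seq) - len(g.seq) % 3]
            raw = str(Seq(nt).translate(table=11))
            raw = raw.rstrip("*")
            internal = "*" in raw
            prot = raw.split("*", 1)[0] if internal else raw
        if not prot:
            continue
        out.append(
            GeneSequence(
                genome_id=g.genome_id,
                key=g.key,
                seq=prot,
                kind="protein",
                internal_stop=internal,
            )
        )
    return out


def _builtin_aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "nucleotide":
        aligner.match_score = 2
        aligner.mismatch_score = -3
        # a gap of length k costs 5 + 2k
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
    return aligner


def _builtin_all_vs_all(
    queries: Sequence[GeneSequence], evalue_threshold: float
) -> list[RawHit]:
    kind = queries[0].kind
    lam, k_const = _KA_PARAMS[kind]
    aligner = _builtin_aligner(kind)
    total_len = sum(len(q.seq) for q in queries)
    hits: list[RawHit] = []
    for q in queries:
        for s in queries:
            if s.genome_id == q.genome_id:
                continue
            alignment = aligner.align(q.seq, s.seq)[0]
            score = float(alignment.score)
            if score <= 0:
                continue
            evalue = k_const * len(q.seq) * (total_len - len(q.seq)) * math.exp(
                -lam * score
            )
            if evalue > evalue_threshold:
                continue
            counts = alignment.counts()
            length = int(alignment.length)
            identity = 100.0 * counts.identities / length if length else 0.0
            hits.append(
                RawHit(
                    query_genome=q.genome_id,
                    query_key=q.key,
                    subject_genome=s.genome_id,
                    subject_key=s.key,
                    percent_identity=identity,
                    alignment_length=length,
                    bitscore=score,
                    evalue=evalue,
                )
            )
    return hits


def _write_fasta(seqs: Sequence[GeneSequence], path: Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            if "|" in s.key or "|" in s.genome_id:
                raise ValueError(f"'|' not allowed in identifiers: {s.genome_id}|{s.key}")
            fh.write(f">{s.genome_id}|{s.key}\n{s.seq}\n")


def _external_all_vs_all(
    queries: Sequence[GeneSequence],
    mode: str,
    evalue_threshold: float,
    work_dir: Optional[Path] = None,
) -> list[RawHit]:
    prog = "blastn" if mode == "blastn" else "blastp"
    for binary in (prog, "makeblastdb"):
        if shutil.which(binary) is None:
            raise RuntimeError(
                f"BLAST+ binary '{binary}' not found on PATH; install BLAST+ "
                "or use engine='builtin'"
            )
    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    wd = Path(ctx.name) if ctx else Path(work_dir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        fasta = wd / "genes.fasta"
        _write_fasta(queries, fasta)
        db = wd / "genesdb"
        dbtype = "nucl" if prog == "blastn" else "prot"
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", dbtype, "-out", str(db)],
            check=True,
            capture_output=True,
        )
        cmd = [
            prog,
            "-query",
            str(fasta),
            "-db",
            str(db),
            "-outfmt",
            "6 qseqid sseqid pident length bitscore evalue",
            "-evalue",
            str(evalue_threshold),
        ]
        if prog == "blastn":
            cmd += ["-task", "blastn"]
        result = subprocess.run(cmd, check=True, capture_output=True, text=True)
        hits: list[RawHit] = []
        for line in result.stdout.splitlines():
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 6:
                continue
            qg, qk = cols[0].split("|", 1)
            sg, sk = cols[1].split("|", 1)
            if qg == sg:
                continue
            hits.append(
                RawHit(
                    query_genome=qg,
                    query_key=qk,
                    subject_genome=sg,
                    subject_key=sk,
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    bitscore=float(cols[4]),
                    evalue=float(cols[5]),
                )
            )
        return hits
    finally:
        if ctx:
            ctx.cleanup()


def all_vs_all(
    queries: Sequence[GeneSequence],
    mode: Literal["blastn", "blastp"] = "blastn",
    engine: Literal["external", "builtin"] = "builtin",
    evalue_threshold: float = DEFAULT_EVALUE,
    work_dir: Optional[str | Path] = None,
) -> list[RawHit]:
    """Search every gene against the gene set of every other genome.

    Self-genome comparisons are excluded, so downstream "unique" means
    "no match in any other genome".  Hits with e-value above
    ``evalue_threshold`` are discarded.
    """
    if not queries:
        return []
    kinds = {q.kind for q in queries}
    if len(kinds) > 1:
        raise ValueError(f"mixed sequence kinds in input: {sorted(kinds)}")
    expected = "nucleotide" if mode == "blastn" else "protein"
    if kinds != {expected}:
        raise ValueError(f"mode {mode} requires {expected} sequences, got {kinds}")
    if engine == "builtin":
        return _builtin_all_vs_all(queries, evalue_threshold)
    return _external_all_vs_all(
        queries, mode, evalue_threshold, Path(work_dir) if work_dir else None
    )


def summarize_best_hits(hits: Sequence[RawHit]) -> pd.DataFrame:
    """Keep the single best hit per (query gene, subject genome).

    Multiple HSPs between the same gene pair collapse to the best one
    first; selection is by maximal bitscore with a deterministic
    tie-break: greater alignment length, then smaller e-value, then
    lexicographically smaller subject key.
    """
    df = pd.DataFrame([vars(h) for h in hits], columns=BEST_HIT_COLUMNS)
    if df.empty:
        return df
    df = df.sort_values(
        by=["bitscore", "alignment_length", "evalue", "subject_key"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    df = df.drop_duplicates(
        subset=["query_genome", "query_key", "subject_genome"], keep="first"
    )
    df = df.sort_values(
        ["query_genome", "query_key", "subject_genome"], kind="mergesort"
    ).reset_index(drop=True)
    df["alignment_length"] = df["alignment_length"].astype("int64")
    return df
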