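"""Synthetic genome sets with a known homology manifest.

The generator emits small GenBank genomes whose gene content is planted
by construction: *core* genes present in every genome as exact copies,
*shared blocks* of genes present in a stated genome subset at a
controlled percent identity (point substitutions relative to an
unmutated reference copy), and *unique* genes screened to share no
11-mer with any gene of any other genome.  The accompanying manifest
records gene family membership, coordinates, strands and planted
identities, and is the independent oracle for every downstream
conservation statistic.

These fixtures test the pipeline's accounting; they do not model phage
evolution (no recombination, no mosaicism, uniform base composition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_UNIQUE_KMER = 11  # exact-match word length used to screen unique genes


@dataclass
class SharedBlock:
    """A block of genes shared by a genome subset at a target identity.

    ``genomes`` are 0-based genome indices; the first listed genome
    carries the unmutated reference copy of each gene, the others carry
    copies mutated to ``identity`` percent relative to that reference.
    """

    n_genes: int
    genomes: tuple[int, ...]
    identity: float  # percent, in (50, 100]


@dataclass
class FixtureSpec:
    n_genomes: int = 4
    n_core: int = 3
    shared_blocks: list[SharedBlock] = field(default_factory=list)
    n_unique_per_genome: int = 1
    gene_length_range: tuple[int, int] = (300, 450)  # bp, multiples of 3
    intergenic_range: tuple[int, int] = (40, 120)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.n_core < 0 or self.n_unique_per_genome < 0:
            raise ValueError("gene counts must be >= 0")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo < 30 or hi < lo:
            raise ValueError("gene_length_range must be multiples of 3, >= 30")
        for blk in self.shared_blocks:
            if not (50.0 < blk.identity <= 100.0):
                raise ValueError("block identity must be in (50, 100]")
            if len(set(blk.genomes)) < 2:
                raise ValueError("a shared block needs >= 2 distinct genomes")
            if any(g < 0 or g >= self.n_genomes for g in blk.genomes):
                raise ValueError("block genome index out of range")


@dataclass
class GeneEntry:
    genome_id: str
    key: str
    family: str
    start: int
    end: int
    strand: str
    sequence: str  # 5'->3' gene orientation
    translation: str
    planted_identity: float  # percent identity to the family reference copy


@dataclass
class FixtureManifest:
    """Ground truth for a generated genome set."""

    genome_ids: list[str]
    genes: list[GeneEntry]
    seed: int

    def families(self) -> dict[str, list[GeneEntry]]:
        fams: dict[str, list[GeneEntry]] = {}
        for g in self.genes:
            fams.setdefault(g.family, []).append(g)
        return fams

    def genes_of(self, genome_id: str) -> list[GeneEntry]:
        return [g for g in self.genes if g.genome_id == genome_id]

    def unique_keys(self, genome_id: str) -> list[str]:
        """Keys of genes whose family has no member in any other genome."""
        fams = self.families()
        return [
            g.key
            for g in self.genes_of(genome_id)
            if all(m.genome_id == genome_id for m in fams[g.family])
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "genome_ids": self.genome_ids,
                "genes": [vars(g) for g in self.genes],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        d = json.loads(text)
        return cls(
            genome_ids=list(d["genome_ids"]),
            genes=[GeneEntry(**g) for g in d["genes"]],
            seed=int(d["seed"]),
        )


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS: ATG start, no internal stop, TAA terminator."""
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, identity: float
) -> tuple[str, int]:
    """Plant point substitutions to reach a target percent identity.

    Mutation count is ``round((1 - identity/100) * len)``.  Codon
    position 3 is preferred (silent-ish), positions are drawn without
    replacement, internal codons only, and any substitution creating an
    in-frame stop is re-drawn so protein fixtures stay valid.
    """
    n_mut = int(round((1.0 - identity / 100.0) * len(seq)))
    chars = list(seq)
    n_codons = len(seq) // 3
    # candidate positions: codon pos 3 first, then pos 1/2; skip start/stop codons
    third = [3 * c + 2 for c in range(1, n_codons - 1)]
    other = [3 * c + o for c in range(1, n_codons - 1) for o in (0, 1)]
    order = list(rng.permutation(third)) + list(rng.permutation(other))
    mutated = 0
    for pos in order:
        if mutated >= n_mut:
            break
        old = chars[pos]
        choices = [b for b in _BASES if b != old]
        rng.shuffle(choices)
        for new in choices:
            chars[pos] = new
            codon = "".join(chars[3 * (pos // 3) : 3 * (pos // 3) + 3])
            if codon not in _STOPS:
                mutated += 1
                break
            chars[pos] = old
    return "".join(chars), mutated


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(seq: str) -> str:
    return str(Seq(seq).translate(table=11)).rstrip("*")


def generate_genome_set(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write ``spec.n_genomes`` GenBank files plus ``manifest.json``.

    Each genome carries gene+CDS feature pairs with locus_tags
    ``G<i>_<j>`` and protein_ids ``P<i>_<j>.1``; the returned manifest
    exactly describes the emitted files.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lo, hi = spec.gene_length_range

    def gene_len() -> int:
        return int(rng.integers(lo // 3, hi // 3 + 1)) * 3

    # family reference sequences
    core_refs = {f"core{i}": _random_cds(rng, gene_len()) for i in range(spec.n_core)}
    block_refs: list[dict[str, str]] = []
    for b, blk in enumerate(spec.shared_blocks):
        block_refs.append(
            {f"blk{b}_{i}": _random_cds(rng, gene_len()) for i in range(blk.n_genes)}
        )

    # per-genome gene lists: (family, sequence, planted_identity)
    per_genome: list[list[tuple[str, str, float]]] = [
        [] for _ in range(spec.n_genomes)
    ]
    for fam, ref in core_refs.items():
        for gi in range(spec.n_genomes):
            per_genome[gi].append((fam, ref, 100.0))
    for blk, refs in zip(spec.shared_blocks, block_refs):
        for fam, ref in refs.items():
            for rank, gi in enumerate(blk.genomes):
                if rank == 0:
                    per_genome[gi].append((fam, ref, 100.0))
                else:
                    mut, _ = _mutate_to_identity(rng, ref, blk.identity)
                    per_genome[gi].append((fam, mut, blk.identity))

    # unique genes, screened for shared k-mers against every other gene
    # (both strands) already placed anywhere in the set
    shared_kmers: set[str] = set()
    for genes in per_genome:
        for _, seq, _ in genes:
            shared_kmers |= _kmers(seq, _UNIQUE_KMER)
            shared_kmers |= _kmers(_revcomp(seq), _UNIQUE_KMER)
    unique_pool: list[list[tuple[str, str, float]]] = [[] for _ in range(spec.n_genomes)]
    taken = set(shared_kmers)
    for gi in range(spec.n_genomes):
        for j in range(spec.n_unique_per_genome):
            for _attempt in range(200):
                cand = _random_cds(rng, gene_len())
                km = _kmers(cand, _UNIQUE_KMER) | _kmers(_revcomp(cand), _UNIQUE_KMER)
                if not (km & taken):
                    taken |= km
                    unique_pool[gi].append((f"uniq{gi}_{j}", cand, 100.0))
                    break
            else:  # pragma: no cover - astronomically unlikely at these sizes
                raise RuntimeError("could not draw a k-mer-unique gene")

    genome_ids = [f"SYNG{gi:02d}" for gi in range(spec.n_genomes)]
    manifest = FixtureManifest(genome_ids=genome_ids, genes=[], seed=spec.seed)

    for gi, genome_id in enumerate(genome_ids):
        genes = per_genome[gi] + unique_pool[gi]
        order = rng.permutation(len(genes))
        seq_parts: list[str] = []
        pos = int(rng.integers(*spec.intergenic_range))
        seq_parts.append("".join(rng.choice(list(_BASES), size=pos)))
        features: list[SeqFeature] = []
        for j, idx in enumerate(order):
            fam, gseq, ident = genes[idx]
            strand = 1 if rng.random() < 0.7 else -1
            placed = gseq if strand == 1 else _revcomp(gseq)
            start, end = pos, pos + len(gseq)
            locus = f"G{gi}_{j}"
            quals_gene = {"locus_tag": [locus], "gene": [fam]}
            quals_cds = {
                "locus_tag": [locus],
                "gene": [fam],
                "protein_id": [f"P{gi}_{j}.1"],
                "product": [f"{fam} protein"],
                "translation": [_translate(gseq)],
                "transl_table": ["11"],
            }
            loc = SimpleLocation(start, end, strand=strand)
            features.append(SeqFeature(loc, type="gene", qualifiers=quals_gene))
            features.append(SeqFeature(loc, type="CDS", qualifiers=quals_cds))
            seq_parts.append(placed)
            gap = int(rng.integers(*spec.intergenic_range))
            seq_parts.append("".join(rng.choice(list(_BASES), size=gap)))
            pos = end + gap
            manifest.genes.append(
                GeneEntry(
                    genome_id=genome_id,
                    key=locus,
                    family=fam,
                    start=start,
                    end=end,
                    strand="+" if strand == 1 else "-",
                    sequence=gseq,
                    translation=_translate(gseq),
                    planted_identity=float(ident),
                )
            )
        full_seq = "".join(seq_parts)
        record = SeqRecord(
            Seq(full_seq),
            id=genome_id,
            name=genome_id,
            description=f"synthetic fixture genome {genome_id}",
        )
        record.annotations["molecule_type"] = "DNA"
        record.annotations["topology"] = "linear"
        record.annotations["date"] = "01-JAN-1980"
        record.features = sorted(features, key=lambda f: int(f.location.start))
        SeqIO.write(record, str(out_dir / f"{genome_id}.gb"), "genbank")

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def expected_conservation(
    manifest: FixtureManifest,
    selection: Optional[Sequence[str]] = None,
) -> "pd.DataFrame":
    """Brute-force expected match counts from family membership.

    For every gene of every selected genome, counts the *other* selected
    genomes containing at least one member of the same family.  This is
    the oracle the pipeline's ``match_count_in_set`` is checked against.
    """
    import pandas as pd

    genomes = list(selection) if selection is not None else list(manifest.genome_ids)
    unknown = set(genomes) - set(manifest.genome_ids)
    if unknown:
        raise ValueError(f"selection names unknown genomes: {sorted(unknown)}")
    fams = manifest.families()
    rows = []
    for g in manifest.genes:
        if g.genome_id not in genomes:
            continue
        others = {
            m.genome_id
            for m in fams[g.family]
            if m.genome_id != g.genome_id and m.genome_id in genomes
        }
        rows.append(
            {
                "genome_id": g.genome_id,
                "key": g.key,
                "expected_match_count": len(others),
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "key", "expected_match_count"])
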