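# Methods

## Pipeline model

The pipeline treats a comparative set of phage genomes as a collection
of annotated genes and asks, for each gene, in how many of the other
genomes a homologue can be found. It runs in four steps — load/download,
validate, search, plot — with every intermediate result stored as a
Parquet table so later steps (in particular plotting) never recompute
earlier ones.

### Ingest and identifier resolution

GenBank files are parsed with Biopython. Coordinates are converted
once, at the parse boundary, from GenBank's 1-based inclusive
convention to 0-based half-open intervals; compound (`join`) locations
are collapsed to their outermost bounds for plotting, with the exact
segments retained and stitched for sequence extraction and
translation. Feature types other than `gene`/`CDS` are kept in the raw
table (`genbank_df`) but excluded from homology and plotting.

Each genome's stable gene identifier (the *key* used by all joins and
plots) depends on its annotation style:

* files with `gene` features → `locus_tag`;
* files with only `CDS` features → `protein_id`;
* per-feature fallback chain `locus_tag` → `protein_id` → gene name,
  so a nearly complete file degrades gracefully instead of being
  rejected outright.

A locus commonly appears as *both* a `gene` and a `CDS` feature
sharing one `locus_tag`. The raw table keeps both rows (one row per
source feature); the processed table (`processed_genbank_df`) merges
them into one keyed row per locus, attaching the CDS's `protein_id`,
`product` and `translation` and using the CDS interval as the coding
region. This makes the processed table unique on `(genome_id, key)`,
which every downstream join relies on.

Validation is total: any parseable file yields a report (checks:
non-empty sequence, presence of coding features, identifier
availability, identifier uniqueness, no `|` in identifiers — `|`
delimits genome and key in intermediate FASTA headers). Failures
reject the genome with a logged warning; they never abort a
multi-genome run. An unparseable file likewise becomes a rejected
report in the run metadata.

### Homology search

Gene nucleotide sequences are sliced from the genome (minus-strand
genes reverse-complemented, so family members always compare in the
same orientation); proteins come from the GenBank `translation`
qualifier when present, otherwise from translation table 11 (bacteria
and their phages), truncating at internal stops with a flag.

Two engines implement one contract (each gene searched against the
genes of every *other* genome; self-genome hits excluded):

* **external** — BLAST+ `makeblastdb` + `blastn -task blastn` /
  `blastp`, tabular output (`-outfmt 6`) parsed by position. This is
  the production engine for real data.
* **builtin** — global Needleman–Wunsch via
  `Bio.Align.PairwiseAligner`. Nucleotide scoring: match +2, mismatch
  −3, gap of length *k* costs 5 + 2*k*; protein scoring: BLOSUM62, gap
  cost 11 + *k*. The bitscore surrogate is the raw alignment score;
  the e-value surrogate is the Karlin–Altschul form
  `E = K·m·n·exp(−λS)` with fixed constants (nucleotide λ = 0.625,
  K = 0.41; protein λ = 0.267, K = 0.041 — values in the range BLAST
  reports for gapped searches). These constants only need to separate
  genuine homologues (scores in the hundreds, E ≈ 0) from unrelated
  global alignments (score ≤ 0); they are not calibrated statistics.
  Global alignment is appropriate here because the compared units are
  whole genes, not genomic windows.

A raw hit is retained iff e-value ≤ 10⁻³ (configurable). Percent
identity is matches / alignment length × 100 (BLAST convention).
Best-hit reduction keeps one row per (query gene, subject genome):
maximal bitscore, ties broken by greater alignment length, then
smaller e-value, then lexicographically smaller subject key — a total
order, so summary tables are byte-reproducible.

### Conservation and uniqueness

`gene_uniqueness` (or `protein_uniqueness`) is the full grid of
(gene × other genome) rows with the best hit joined on;
`total_match_count` counts distinct matched genomes over the whole
processed set. The per-plot `colour_table` restricts counting to the
plotted selection: `conservation = match_count_in_set / (n − 1)`,
excluding self, so 0 and 1 land exactly on the palette ends ("unique"
and "strictly conserved"). Counting is directional (query → subject);
reciprocal agreement is not enforced. No identity floor is applied to
counting — the e-value screen is the only match criterion; an identity
floor affects only which cross-links are drawn.

### Rendering

Tracks are drawn in selection order, left-aligned, to a shared
base-pair scale (no length normalisation). A reverse-oriented genome
of length *L* draws each gene `[s, e)` at `[L−e, L−s)` with flipped
arrowheads — an involution, so reversing twice restores the forward
rendering. Cross-links connect a gene to its best hit on the adjacent
track only; both query directions between the adjacent pair are
considered and reciprocal duplicates collapse by unordered gene pair.
Gene fills come from the conservation palette (default yellow → green
→ blue → purple); link fills from a light-grey → dark-red identity
gradient. Palettes are piecewise-linear RGB interpolations over evenly
spaced hex stops, exact at the endpoints.

Geometry is computed once into primitive shapes; an SVG writer
serialises them with fixed two-decimal formatting so identical inputs
give byte-identical SVG, and the PNG output is drawn from the same
shapes through matplotlib (rather than rasterising the SVG file, which
would require an SVG rasteriser; sharing the geometry keeps the two
formats consistent by construction). Default PNG resolution is
300 dpi.

### NCBI download

A thin Entrez eutils client (esearch + efetch, `rettype=gb`) with an
injectable transport: tests run against canned responses, production
goes over HTTPS with urllib. NCBI requires a contact email; an API key
(argument or `NCBI_API_KEY`) raises the polite request rate from 3/s
to 10/s. Transient failures retry three times with exponential
backoff; downloads are idempotent (existing files are skipped without
`--force`). Default `max_records` is 100.

## Synthetic genome sets

The fixture generator emits GenBank genomes whose homology is known by
construction, so every pipeline statistic can be checked against an
independent brute-force oracle:

* **core genes** — exact copies present in every genome;
* **shared blocks** — genes present in a stated genome subset at a
  controlled identity. The first genome of the subset carries the
  unmutated reference; other members carry copies with
  `round((1 − identity)·length)` point substitutions, placed at codon
  position 3 preferentially and re-drawn if they would create an
  in-frame stop (so protein fixtures stay valid). Planted identity is
  therefore reference↔member; two mutated members of the same block
  are further apart, which the manifest records per gene;
* **unique genes** — random coding sequences screened to share no
  exact 11-mer (either strand) with any gene of any other genome. The
  11-mer screen is a fixture property guaranteeing undetectability at
  BLAST's default nucleotide word size, not a biological claim.

Genes are placed in shuffled order with random intergenic spacers and
random strands; defaults are 2–8 genomes, 3 core genes, one unique
gene per genome, gene lengths 300–450 bp, intergenic gaps 40–120 bp,
block identities in (50, 100]. Everything is deterministic given the
seed, down to the emitted bytes.

What the fixtures do **not** model: recombination and mosaic descent,
insertions/deletions between homologues (planted divergence is
substitution-only), skewed base composition, annotation errors, or
paralogy (each family has at most one member per genome). Passing
tests therefore demonstrate the pipeline's *accounting* — extraction,
search plumbing, best-hit reduction, counting, rendering — not
sensitivity of homology detection on real, indel-rich phage data,
where the external BLAST engine is the appropriate tool.

## Problem sizes and numerical choices

The test-suite and acceptance-script runs use sets of 3–8 genomes with
5–6 genes each (300–420 bp), chosen as the smallest sets that exercise
every conservation class (core, multi-genome block, pairwise block,
unique) in every selection; the builtin engine completes such a set in
seconds. Planted identities (75–90%) sit well above the detection
floor of global alignment at these lengths, where recovery is exact;
below ~70% the builtin e-value screen begins to lose planted pairs,
which is a property of the surrogate statistics, not of the external
BLAST path.

Other conventions: features sort by (start, end, type); stable
mergesort everywhere sorting affects output; parquet written without
index; gene arrows shorter than the arrowhead render as boxes; genes
overlapping on a track draw in file order, last on top.

## Known limitations

* Conservation is pairwise-best-hit based; there is no orthology
  clustering, so two different genes of genome B may both count as
  "the" match of two genes of A.
* Directional counting means a gene can count B as matched while B's
  best hit points elsewhere.
* The builtin engine's e-values are surrogates; do not compare them
  numerically with BLAST's.
* GenBank input only; no EMBL/GFF3, no re-annotation of unannotated
  sequence.
* Tracks are left-aligned (configurable scale, not configurable
  centring); no interactive output.
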