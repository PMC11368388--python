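# synteny-conserve

Stacked linear synteny diagrams for sets of annotated phage genomes,
colour-coded by gene conservation.

Phage genomes are mosaic: a genus typically shares a backbone of core
structural genes while individual isolates carry unique accessory genes
that can alter host phenotypes. Seeing, at a glance, which genes of a
genome are strictly conserved across a set of related phages and which
are unique to one isolate is the question this package answers. It
takes annotated GenBank files (local, or downloaded from NCBI by an
Entrez query), computes per-gene homology across all genomes, derives
conservation statistics over any chosen subset, and renders a diagram
in which every gene arrow is coloured by its conservation level and
ribbons between adjacent genomes are shaded by percent identity.

## Method

The unit of comparison is the gene. For every annotated gene *g* of
genome *A* and every other genome *B*, an all-vs-all search (BLAST+ or
a builtin Needleman–Wunsch engine) finds the **best hit**: the single
highest-bitscore match of *g* among *B*'s genes, retained when its
e-value ≤ 10⁻³. Over a plotted selection of *n* genomes, each gene's
conservation is

```
conservation(g) = m / (n − 1)
```

where *m* is the number of *other* selected genomes containing a best
hit for *g*. A gene with conservation 0 is **unique** within the set
(yellow, by default), 1 is **strictly conserved** (purple), and values
between are partially conserved (green–blue). Cross-links are drawn
between a gene and its best hit on the adjacent track and shaded by
percent identity (identical columns / alignment length × 100).

All intermediate tables are Apache Parquet
(`genbank_df`, `processed_genbank_df`, `blastn_summary` /
`blastp_summary`, `gene_uniqueness` / `protein_uniqueness`,
`colour_table`), so results can be queried with pandas, polars or
DuckDB, and any number of plots can be drawn from one computation —
changing the selection, orientation or palette never re-runs the
search.

## Worked example

The package ships a generator for synthetic genome sets with known
(planted) homology, which doubles as a quick demo:

```
$ synteny-conserve fixtures --out data/genbank --seed 42
wrote 4 genomes (20 genes) to data/genbank
$ synteny-conserve validate --data-dir data
validated 4 genome(s); 4 accepted
$ synteny-conserve blastn --data-dir data
blastn: 40 best hits
$ printf 'sequence,orientation\nSYNG00,1\nSYNG01,1\nSYNG02,0\nSYNG03,1\n' > selection.csv
$ synteny-conserve plot --data-dir data --selection selection.csv \
      --title "Demo phage set" --format svg,png
wrote data/plots/synteny/synteny.svg
wrote data/plots/synteny/synteny.png
wrote data/plots/synteny/colour_table.parquet
$ synteny-conserve status --data-dir data
validate   ok   genbank_df.parquet, processed_genbank_df.parquet
blastn     ok   blastn_summary.parquet, gene_uniqueness.parquet
plot       ok   synteny.svg, synteny.png, colour_table.parquet
```

The selection CSV lists the plotted genomes top-to-bottom with their
orientation (1 = forward, 0 = reverse-complemented track). The colour
table written next to each plot answers "which genes are unique?"
directly:

```python
>>> import pandas as pd
>>> from synteny_conserve.conservation import query_unique_genes, query_gene_matches
>>> colour = pd.read_parquet("data/plots/synteny/colour_table.parquet")
>>> query_unique_genes(colour, "SYNG00")
 key gene_name         product  start  end
G0_5   uniq0_0 uniq0_0 protein   2418  2850
```

i.e. genome SYNG00 carries exactly one gene (locus `G0_5`) with no
match in any other plotted genome — which is the one unique gene the
generator planted. The reverse query lists where a gene of interest is
conserved and under which locus tag:

```python
>>> uniq = pd.read_parquet("data/tables/gene_uniqueness.parquet")
>>> query_gene_matches(uniq, "core0", "SYNG00")
subject_genome subject_key  percent_identity
        SYNG01        G1_2             100.0
        SYNG02        G2_1             100.0
        SYNG03        G3_1             100.0
```

`core0` has a 100%-identity match in all three other genomes: strictly
conserved. For real data, replace the fixtures step with your own
`.gb`/`.gbk` files in `data/genbank/`, or download a set:

```
synteny-conserve download --data-dir data \
    --search-key '"Spbetavirus"[Organism] AND complete genome[Title] AND phage[Title]' \
    --email you@example.org
```

(NCBI requires a contact email; an API key is read from
`NCBI_API_KEY`.) `scripts/reproduce_spbetavirus.py` automates that
published example end to end — network required.

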