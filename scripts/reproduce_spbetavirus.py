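"""Best-effort reproduction of the published SPbetavirus worked example.

Requires network access to NCBI (and optionally BLAST+ for the external
engine).  Downloads the genus set with the Entrez query

    "Spbetavirus"[Organism] AND complete genome[Title] AND phage[Title]

runs validate + blastn, plots a 10-genome selection, and reports the
unique genes of MT601272 — expected to be six genes, all annotated as
hypothetical proteins.  The result depends on current NCBI holdings
for the query, so this is an integration check, not part of the
offline test suite.

    python scripts/reproduce_spbetavirus.py --email you@example.org \
        --data-dir scratch/spbeta [--engine external]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from synteny_conserve import pipeline
from synteny_conserve.conservation import SequenceSelection, compute_colour_table, query_unique_genes
from synteny_conserve.ncbi import DownloadRequest
from synteny_conserve.plot import PlotConfig, plot_job

QUERY = '"Spbetavirus"[Organism] AND complete genome[Title] AND phage[Title]'
FOCUS = "MT601272"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="contact email for Entrez")
    parser.add_argument("--data-dir", type=Path, default=Path("scratch/spbeta"))
    parser.add_argument("--engine", choices=["builtin", "external"], default="external")
    parser.add_argument("--max-records", type=int, default=20)
    args = parser.parse_args()

    req = DownloadRequest(
        search_key=QUERY, email=args.email, max_records=args.max_records
    )
    files = pipeline.download_job(args.data_dir, req)
    print(f"downloaded {len(files)} GenBank records")

    result = pipeline.validate_job(args.data_dir)
    accepted = [rep.genome_id for rep in result["reports"] if rep.ok]
    print(f"accepted genomes: {accepted}")

    pipeline.blast_job(args.data_dir, mode="blastn", engine=args.engine)

    plotted = [g for g in accepted][:10]
    sel = args.data_dir / "selection.csv"
    sel.write_text(
        "sequence,orientation\n" + "\n".join(f"{g},1" for g in plotted) + "\n"
    )
    out = plot_job(
        args.data_dir,
        sel,
        config=PlotConfig(title="SPbetavirus synteny", output_formats=("svg", "png")),
    )
    print(f"plot written: {out['plots']}")

    import pandas as pd

    uniq = pd.read_parquet(args.data_dir / "tables" / "gene_uniqueness.parquet")
    selection = SequenceSelection([(g, "forward") for g in plotted])
    colour = compute_colour_table(uniq, selection)
    focus = next((g for g in plotted if g.startswith(FOCUS)), None)
    if focus is None:
        print(f"{FOCUS} not among plotted genomes; holdings may have changed")
        return
    unique = query_unique_genes(colour, focus)
    print(f"{focus}: {len(unique)} unique genes within the plotted set")
    print(unique.to_string(index=False))
    n_hypo = unique["product"].fillna("").str.contains("hypothetical", case=False).sum()
    print(f"{n_hypo}/{len(unique)} annotated as hypothetical proteins")


if __name__ == "__main__":
    main()
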