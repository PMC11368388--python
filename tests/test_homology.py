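"""Gene sequence extraction, translation, search engines, best hits."""

import pandas as pd
import pytest

from synteny_conserve.fixtures import FixtureSpec, SharedBlock, generate_genome_set
from synteny_conserve.homology import (
    GeneSequence,
    RawHit,
    all_vs_all,
    extract_gene_sequences,
    summarize_best_hits,
    translate_genes,
)
from synteny_conserve.ingest import GenomeRecord, load_genbank_dir
from synteny_conserve import pipeline


def _gene_df(rows):
    cols = [
        "genome_id", "key", "start", "end", "strand", "segments", "translation",
    ]
    return pd.DataFrame(rows, columns=cols)


class TestExtraction:
    def test_forward_slice_and_reverse_complement(self):
        rec = GenomeRecord("G", "", "ATGAAACCC", [])
        df = _gene_df(
            [
                ("G", "f", 0, 6, "+", "[[0, 6]]", None),
                ("G", "r", 0, 6, "-", "[[0, 6]]", None),
            ]
        )
        seqs = {s.key: s.seq for s in extract_gene_sequences(df, [rec])}
        assert seqs == {"f": "ATGAAA", "r": "TTTCAT"}

    def test_compound_location_stitches_segments(self):
        rec = GenomeRecord("G", "", "ATGAAACCCGGGTTT", [])
        df = _gene_df([("G", "j", 0, 12, "+", "[[0, 3], [9, 12]]", None)])
        (s,) = extract_gene_sequences(df, [rec])
        assert s.seq == "ATGGGG"

    def test_out_of_bounds_interval_names_gene(self):
        rec = GenomeRecord("G", "", "ATG", [])
        df = _gene_df([("G", "bad", 0, 99, "+", "[[0, 99]]", None)])
        with pytest.raises(ValueError, match="bad"):
            extract_gene_sequences(df, [rec])

    def test_fixture_sequences_match_manifest(self, run_env):
        seqs = extract_gene_sequences(run_env.processed, run_env.records)
        got = {(s.genome_id, s.key): s.seq for s in seqs}
        for entry in run_env.manifest.genes:
            assert got[(entry.genome_id, entry.key)] == entry.sequence


class TestTranslation:
    def test_bacterial_code_and_stop_removal(self):
        g = GeneSequence("G", "k", "ATGAAATAA", "nucleotide")
        (p,) = translate_genes([g])
        assert p.seq == "MK"
        assert p.kind == "protein"

    def test_genbank_qualifier_takes_precedence(self):
        g = GeneSequence("G", "k", "ATGAAATAA", "nucleotide", provided_translation="MKLV")
        (p,) = translate_genes([g])
        assert p.seq == "MKLV"

    def test_internal_stop_truncates_and_flags(self):
        g = GeneSequence("G", "k", "ATGTAAAAATAA", "nucleotide")
        (p,) = translate_genes([g])
        assert p.seq == "M"
        assert p.internal_stop

    def test_non_codon_length_truncated(self):
        g = GeneSequence("G", "k", "ATGAAAC", "nucleotide")
        (p,) = translate_genes([g])
        assert p.seq == "MK"

    def test_protein_input_rejected(self):
        with pytest.raises(ValueError, match="nucleotide"):
            translate_genes([GeneSequence("G", "k", "MK", "protein")])

    def test_fixture_translations_match_manifest(self, run_env):
        genes = extract_gene_sequences(run_env.processed, run_env.records)
        prots = {(p.genome_id, p.key): p.seq for p in translate_genes(genes)}
        for entry in run_env.manifest.genes:
            assert prots[(entry.genome_id, entry.key)] == entry.translation


class TestAllVsAll:
    def test_identical_genes_hit_at_100_both_ways(self):
        seqs = [
            GeneSequence("A", "g1", "ATGAAACCCGGGTTTACGTAA", "nucleotide"),
            GeneSequence("B", "h1", "ATGAAACCCGGGTTTACGTAA", "nucleotide"),
        ]
        hits = all_vs_all(seqs, engine="builtin")
        assert {(h.query_genome, h.subject_genome) for h in hits} == {("A", "B"), ("B", "A")}
        assert all(h.percent_identity == 100.0 for h in hits)

    def test_unique_gene_produces_no_hits(self, run_env):
        summary = run_env.summary
        for gid in run_env.manifest.genome_ids:
            for key in run_env.manifest.unique_keys(gid):
                sub = summary[
                    (summary["query_genome"] == gid) & (summary["query_key"] == key)
                ]
                assert sub.empty

    def test_planted_identity_recovered_within_5_points(self, run_env):
        summary = run_env.summary
        fams = run_env.manifest.families()
        for entry in run_env.manifest.genes:
            if entry.planted_identity >= 100.0:
                continue
            ref = next(m for m in fams[entry.family] if m.planted_identity == 100.0)
            row = summary[
                (summary["query_genome"] == entry.genome_id)
                & (summary["query_key"] == entry.key)
                & (summary["subject_genome"] == ref.genome_id)
            ]
            assert len(row) == 1
            assert abs(row["percent_identity"].iloc[0] - entry.planted_identity) <= 5.0

    def test_mixed_kind_input_rejected(self):
        seqs = [
            GeneSequence("A", "g", "ATG", "nucleotide"),
            GeneSequence("B", "h", "MK", "protein"),
        ]
        with pytest.raises(ValueError, match="mixed"):
            all_vs_all(seqs)

    def test_self_genome_comparisons_excluded(self, run_env):
        assert (run_env.summary["query_genome"] != run_env.summary["subject_genome"]).all()

    def test_cardinality_bound(self, run_env):
        n_genes = len(run_env.processed)
        n_genomes = len(run_env.manifest.genome_ids)
        assert len(run_env.summary) <= n_genes * (n_genomes - 1)

    def test_duplicated_genome_yields_full_100_identity(self, tmp_path):
        """Byte-identical genomes under two ids: every gene matches at 100%."""
        spec = FixtureSpec(n_genomes=2, n_core=4, n_unique_per_genome=0, seed=2)
        generate_genome_set(spec, tmp_path / "genbank")
        pipeline.validate_job(tmp_path)
        out = pipeline.blast_job(tmp_path, mode="blastn", engine="builtin")
        s = out["summary"]
        assert len(s) == 8  # 4 genes x 2 directions
        assert (s["percent_identity"] == 100.0).all()


class TestBestHits:
    def _hit(self, qk="q", sg="B", sk="s", pid=90.0, alen=100, bits=50.0, ev=1e-30):
        return RawHit("A", qk, sg, sk, pid, alen, bits, ev)

    def test_max_bitscore_selected(self):
        hits = [
            self._hit(sk="s1", bits=50),
            self._hit(sk="s2", bits=75),
            self._hit(sk="s3", bits=60),
        ]
        df = summarize_best_hits(hits)
        assert df["subject_key"].tolist() == ["s2"]

    def test_empty_input_gives_empty_table(self):
        assert summarize_best_hits([]).empty

    def test_tie_breaks_are_deterministic(self):
        # equal bitscore: longer alignment wins; full tie: lex smaller key
        hits = [
            self._hit(sk="zzz", bits=50, alen=120),
            self._hit(sk="aaa", bits=50, alen=100),
        ]
        assert summarize_best_hits(hits)["subject_key"].tolist() == ["zzz"]
        hits = [
            self._hit(sk="zzz", bits=50, alen=100),
            self._hit(sk="aaa", bits=50, alen=100),
        ]
        assert summarize_best_hits(hits)["subject_key"].tolist() == ["aaa"]

    def test_one_row_per_query_subject_genome(self, run_env):
        dup = run_env.summary.duplicated(
            subset=["query_genome", "query_key", "subject_genome"]
        )
        assert not dup.any()

    def test_repeated_runs_byte_identical(self, run_env, tmp_path):
        out = pipeline.blast_job(run_env.dir, mode="blastn", engine="builtin")
        a = tmp_path / "a.parquet"
        b = tmp_path / "b.parquet"
        out["summary"].to_parquet(a, index=False)
        run_env.summary.to_parquet(b, index=False)
        assert a.read_bytes() == b.read_bytes()


class TestExternalEngine:
    def test_blast_plus_agrees_with_builtin(self, tmp_path):
        """External BLAST+ and builtin NW find the same best-hit pairs
        and identities within 5 points on a small planted fixture."""
        spec = FixtureSpec(
            n_genomes=3,
            n_core=2,
            shared_blocks=[SharedBlock(n_genes=1, genomes=(0, 1), identity=80.0)],
            n_unique_per_genome=1,
            seed=5,
        )
        generate_genome_set(spec, tmp_path / "genbank")
        pipeline.validate_job(tmp_path)
        records = load_genbank_dir(tmp_path / "genbank")
        processed = pd.read_parquet(tmp_path / "tables" / "processed_genbank_df.parquet")
        genes = extract_gene_sequences(processed, records)
        builtin = summarize_best_hits(all_vs_all(genes, engine="builtin"))
        external = summarize_best_hits(all_vs_all(genes, engine="external"))
        keys = ["query_genome", "query_key", "subject_genome"]
        assert set(map(tuple, builtin[keys].values)) == set(
            map(tuple, external[keys].values)
        )
        merged = builtin.merge(external, on=keys, suffixes=("_b", "_e"))
        deltas = (merged["percent_identity_b"] - merged["percent_identity_e"]).abs()
        assert (deltas <= 5.0).all()
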