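"""Cross-link computation and synteny diagram rendering."""

import hashlib
import xml.etree.ElementTree as ET

import pandas as pd
import pytest

from synteny_conserve.conservation import (
    SequenceSelection,
    compute_colour_table,
)
from synteny_conserve.plot import (
    CrossLink,
    PlotConfig,
    compute_cross_links,
    plot_job,
    render_synteny,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


def _selection(ids, reverse=()):
    return SequenceSelection(
        [(g, "reverse" if g in reverse else "forward") for g in ids]
    )


def _svg_tracks(svg_path):
    root = ET.parse(svg_path).getroot()
    return [g for g in root.iter(f"{SVG_NS}g") if g.get("class") == "track"]


def _count_links(svg_path):
    root = ET.parse(svg_path).getroot()
    return sum(1 for p in root.iter(f"{SVG_NS}polygon") if p.get("class") == "link")


@pytest.fixture()
def plotted(run_env, selection_csv, tmp_path):
    cfg = PlotConfig(output_formats=("svg",))
    result = plot_job(run_env.dir, selection_csv, config=cfg, out_name=f"p_{tmp_path.name}")
    (svg,) = result["plots"]
    return svg, result["colour_table"]


class TestCrossLinks:
    def test_adjacent_pairs_only(self, run_env):
        sel = _selection(run_env.manifest.genome_ids)
        links = compute_cross_links(run_env.summary, sel)
        ids = sel.genome_ids
        adjacent = set(zip(ids, ids[1:]))
        assert links
        assert {(l.upper_genome, l.lower_genome) for l in links} <= adjacent

    def test_gene_shared_only_across_gap_yields_no_link(self, run_env):
        # the 80% block is shared by SYNG00 and SYNG01; order them apart
        sel = _selection(["SYNG00", "SYNG02", "SYNG01"])
        links = compute_cross_links(run_env.summary, sel)
        block_keys = {
            (g.genome_id, g.key)
            for g in run_env.manifest.genes
            if g.family.startswith("blk0")
        }
        for link in links:
            assert (link.upper_genome, link.upper_key) not in block_keys
            assert (link.lower_genome, link.lower_key) not in block_keys

    def test_identity_floor_filters_links(self, run_env):
        sel = _selection(["SYNG00", "SYNG01"])
        all_links = compute_cross_links(run_env.summary, sel, min_link_identity=0.0)
        strict = compute_cross_links(run_env.summary, sel, min_link_identity=95.0)
        assert len(strict) < len(all_links)
        assert all(l.percent_identity >= 95.0 for l in strict)

    def test_reciprocal_hits_deduplicated(self, run_env):
        sel = _selection(["SYNG00", "SYNG01"])
        links = compute_cross_links(run_env.summary, sel)
        pairs = [(l.upper_key, l.lower_key) for l in links]
        assert len(pairs) == len(set(pairs))


class TestRendering:
    def test_svg_structure_counts(self, run_env, plotted):
        svg, _ = plotted
        tracks = _svg_tracks(svg)
        sel_ids = ["SYNG00", "SYNG01", "SYNG02", "SYNG03"]
        assert [t.get("id") for t in tracks] == [f"track-{g}" for g in sel_ids]
        for track, gid in zip(tracks, sel_ids):
            genes = [
                p for p in track.iter(f"{SVG_NS}polygon") if p.get("class") == "gene"
            ]
            expected = (run_env.processed["genome_id"] == gid).sum()
            assert len(genes) == expected
        links = compute_cross_links(run_env.summary, _selection(sel_ids, reverse={"SYNG02"}))
        assert _count_links(svg) == len(links)

    def test_rerender_is_byte_identical(self, run_env, selection_csv, tmp_path):
        cfg = PlotConfig(output_formats=("svg",))
        r1 = plot_job(run_env.dir, selection_csv, config=cfg, out_name="rr1")
        r2 = plot_job(run_env.dir, selection_csv, config=cfg, out_name="rr2")
        assert r1["plots"][0].read_bytes() == r2["plots"][0].read_bytes()

    def test_png_output_written(self, run_env, selection_csv):
        cfg = PlotConfig(output_formats=("svg", "png"), dpi=72)
        result = plot_job(run_env.dir, selection_csv, config=cfg, out_name="png_case")
        suffixes = {p.suffix for p in result["plots"]}
        assert suffixes == {".svg", ".png"}
        png = next(p for p in result["plots"] if p.suffix == ".png")
        assert png.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"

    def test_reversed_track_mirrors_coordinates(self, run_env, tmp_path):
        """Gene x-extents on a reversed track equal the L-e..L-s mirror."""
        ids = ["SYNG00", "SYNG01"]
        cfg = PlotConfig(output_formats=("svg",))
        uniq = run_env.uniqueness
        colours = compute_colour_table(uniq, _selection(ids))
        fwd = render_synteny(
            run_env.processed, colours, [], _selection(ids), cfg, tmp_path / "fwd"
        )[0]
        rev = render_synteny(
            run_env.processed, colours, [], _selection(ids, reverse={"SYNG01"}),
            cfg, tmp_path / "rev",
        )[0]

        def gene_xs(path, track_id):
            (track,) = [t for t in _svg_tracks(path) if t.get("id") == track_id]
            out = []
            for p in track.iter(f"{SVG_NS}polygon"):
                if p.get("class") == "gene":
                    xs = [float(pt.split(",")[0]) for pt in p.get("points").split()]
                    out.append((min(xs), max(xs)))
            return sorted(out)

        sub = run_env.processed[run_env.processed["genome_id"] == "SYNG01"]
        L = int(sub["end"].max())
        max_len = max(
            int(run_env.processed[run_env.processed["genome_id"] == g]["end"].max())
            for g in ids
        )
        scale = max_len / 900.0
        margin = 130.0
        expected = sorted(
            (margin + (L - e) / scale, margin + (L - s) / scale)
            for s, e in zip(sub["start"], sub["end"])
        )
        got = gene_xs(rev, "track-SYNG01")
        assert len(got) == len(expected)
        for (g1, g2), (e1, e2) in zip(got, expected):
            assert g1 == pytest.approx(e1, abs=0.02)
            assert g2 == pytest.approx(e2, abs=0.02)
        # involution: mirroring twice equals the forward rendering
        assert gene_xs(fwd, "track-SYNG01") != got or L == max_len

    def test_palette_change_keeps_geometry(self, run_env, selection_csv):
        svg1 = plot_job(
            run_env.dir, selection_csv,
            config=PlotConfig(output_formats=("svg",)), out_name="pal1",
        )["plots"][0].read_text()
        svg2 = plot_job(
            run_env.dir, selection_csv,
            config=PlotConfig(output_formats=("svg",), palette="viridis"),
            out_name="pal2",
        )["plots"][0].read_text()
        strip = lambda s: [l.split("fill=")[0] for l in s.splitlines() if "gene" in l]
        assert strip(svg1) == strip(svg2)
        assert svg1 != svg2

    def test_zero_links_still_renders(self, run_env, tmp_path):
        ids = ["SYNG00", "SYNG01"]
        colours = compute_colour_table(run_env.uniqueness, _selection(ids))
        files = render_synteny(
            run_env.processed, colours, [], _selection(ids),
            PlotConfig(output_formats=("svg",)), tmp_path / "nolinks",
        )
        assert _count_links(files[0]) == 0
        assert len(_svg_tracks(files[0])) == 2

    def test_missing_colour_rows_error(self, run_env, tmp_path):
        ids = ["SYNG00", "SYNG01"]
        colours = compute_colour_table(run_env.uniqueness, _selection(ids))
        truncated = colours.iloc[:-1]
        with pytest.raises(ValueError, match="no colour"):
            render_synteny(
                run_env.processed, truncated, [], _selection(ids),
                PlotConfig(output_formats=("svg",)), tmp_path / "x",
            )


class TestPlotJob:
    def test_upstream_tables_untouched_by_replot(self, run_env, selection_csv, tmp_path):
        tables = sorted((run_env.dir / "tables").glob("*.parquet"))
        before = {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in tables}
        plot_job(run_env.dir, selection_csv, out_name="indep1")
        other = tmp_path / "sel2.csv"
        other.write_text("sequence,orientation\nSYNG04,1\nSYNG01,0\nSYNG00,1\n")
        plot_job(run_env.dir, other, out_name="indep2")
        after = {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in tables}
        assert before == after

    def test_colour_table_written_per_plot(self, plotted):
        _, colour_path = plotted
        df = pd.read_parquet(colour_path)
        assert {"genome_id", "key", "match_count_in_set", "conservation_fraction",
                "colour"} <= set(df.columns)

    def test_single_genome_selection_rejected(self, run_env, tmp_path):
        sel = tmp_path / "one.csv"
        sel.write_text("sequence,orientation\nSYNG00,1\n")
        with pytest.raises(ValueError, match="at least 2"):
            plot_job(run_env.dir, sel)

    def test_missing_upstream_names_step(self, tmp_path):
        sel = tmp_path / "sel.csv"
        sel.write_text("sequence,orientation\nA,1\nB,1\n")
        with pytest.raises(FileNotFoundError, match="validate"):
            plot_job(tmp_path, sel)
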