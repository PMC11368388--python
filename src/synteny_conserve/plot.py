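"""Stacked linear synteny diagrams.

One horizontal track per selected genome, in selection order, drawn to
a shared base-pair scale and left-aligned.  Gene glyphs (arrows or
boxes) are filled with the conservation colour from the colour table;
ribbons between adjacent tracks connect a gene to its best hit on the
neighbouring genome and are shaded by percent identity.  Two legend
bars show the identity gradient (cross-links) and the conservation
gradient (genes).

Geometry and style are computed once into a list of primitive shapes;
an SVG backend serialises them with fixed number formatting (identical
inputs give byte-identical SVG) and a PNG backend draws the same
shapes through matplotlib.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from synteny_conserve import artifacts
from synteny_conserve.artifacts import Workspace
from synteny_conserve.conservation import (
    SequenceSelection,
    compute_colour_table,
    read_selection_csv,
)
from synteny_conserve.palettes import PALETTES, colour_for_fraction, colour_for_identity

_TRACK_H = 14.0
_TRACK_GAP = 58.0
_MARGIN_L = 130.0
_MARGIN_R = 30.0
_HEADER_H = 110.0
_PLOT_W = 900.0
_ARROW_HEAD = 6.0
_LEGEND_STEPS = 24


@dataclass
class PlotConfig:
    title: str = "Synteny plot"
    palette: str | Sequence[str] = "conservation"
    identity_palette: str | Sequence[str] = "identity"
    gene_shape: Literal["arrow", "box"] = "arrow"
    output_formats: tuple[str, ...] = ("svg",)
    min_link_identity: float = 0.0
    scale: Optional[float] = None  # bp per drawing unit; None = fit to width
    dpi: int = 300

    def __post_init__(self) -> None:
        if not self.output_formats:
            raise ValueError("at least one output format required")
        bad = set(self.output_formats) - {"svg", "png"}
        if bad:
            raise ValueError(f"unsupported output formats: {sorted(bad)}")
        stops = self.palette_stops
        if stops[0].upper() == stops[-1].upper():
            raise ValueError("palette endpoints must be distinct colours")

    @property
    def palette_stops(self) -> list[str]:
        if isinstance(self.palette, str):
            return PALETTES[self.palette]
        return list(self.palette)

    @property
    def identity_stops(self) -> list[str]:
        if isinstance(self.identity_palette, str):
            return PALETTES[self.identity_palette]
        return list(self.identity_palette)


@dataclass
class CrossLink:
    """A gene-to-best-hit ribbon between two adjacent tracks."""

    upper_genome: str
    upper_key: str
    lower_genome: str
    lower_key: str
    percent_identity: float


def compute_cross_links(
    best_hits: pd.DataFrame,
    selection: SequenceSelection,
    min_link_identity: float = 0.0,
) -> list[CrossLink]:
    """Links between each adjacent track pair of the selection.

    Both query directions between the adjacent pair are considered and
    reciprocal duplicates are collapsed by unordered gene-pair key;
    hits below ``min_link_identity`` are dropped.  Non-adjacent matches
    never produce links.
    """
    links: list[CrossLink] = []
    if best_hits.empty:
        return links
    ids = selection.genome_ids
    for upper, lower in zip(ids, ids[1:]):
        seen: set[tuple[str, str]] = set()
        down = best_hits[
            (best_hits["query_genome"] == upper)
            & (best_hits["subject_genome"] == lower)
        ]
        up = best_hits[
            (best_hits["query_genome"] == lower)
            & (best_hits["subject_genome"] == upper)
        ]
        for row in down.itertuples(index=False):
            pair = (row.query_key, row.subject_key)
            if row.percent_identity < min_link_identity or pair in seen:
                continue
            seen.add(pair)
            links.append(
                CrossLink(upper, row.query_key, lower, row.subject_key,
                          float(row.percent_identity))
            )
        for row in up.itertuples(index=False):
            pair = (row.subject_key, row.query_key)  # (upper_key, lower_key)
            if row.percent_identity < min_link_identity or pair in seen:
                continue
            seen.add(pair)
            links.append(
                CrossLink(upper, row.subject_key, lower, row.query_key,
                          float(row.percent_identity))
            )
    links.sort(
        key=lambda l: (l.upper_genome, l.upper_key, l.lower_genome, l.lower_key)
    )
    return links


# ---------------------------------------------------------------- geometry


@dataclass
class _Shape:
    kind: str  # polygon | rect | line | text
    cls: str
    points: list[tuple[float, float]] = field(default_factory=list)
    fill: str = "none"
    stroke: str = "none"
    opacity: float = 1.0
    text: str = ""
    anchor: str = "start"
    size: float = 11.0


@dataclass
class _Geometry:
    width: float
    height: float
    title: str
    tracks: list[tuple[str, list[_Shape]]]  # (genome_id, shapes)
    links: list[_Shape]
    decorations: list[_Shape]


def _gene_polygon(
    x1: float, x2: float, y: float, strand: str, shape: str
) -> list[tuple[float, float]]:
    h = _TRACK_H / 2.0
    if shape == "box" or (x2 - x1) <= _ARROW_HEAD:
        return [(x1, y - h), (x2, y - h), (x2, y + h), (x1, y + h)]
    if strand == "+":
        xh = x2 - _ARROW_HEAD
        return [(x1, y - h), (xh, y - h), (x2, y), (xh, y + h), (x1, y + h)]
    xh = x1 + _ARROW_HEAD
    return [(x2, y - h), (xh, y - h), (x1, y), (xh, y + h), (x2, y + h)]


def _legend_bar(
    x: float, y: float, w: float, h: float, stops: Sequence[str], label: str
) -> list[_Shape]:
    shapes = [
        _Shape(kind="text", cls="legend-label", points=[(x, y - 4)], text=label,
               fill="#000000", size=10.0)
    ]
    step_w = w / _LEGEND_STEPS
    for i in range(_LEGEND_STEPS):
        frac = i / (_LEGEND_STEPS - 1)
        shapes.append(
            _Shape(
                kind="rect",
                cls="legend-step",
                points=[(x + i * step_w, y), (x + (i + 1) * step_w, y + h)],
                fill=colour_for_fraction(frac, stops),
            )
        )
    shapes.append(
        _Shape(kind="text", cls="legend-tick", points=[(x, y + h + 11)], text="0",
               fill="#000000", size=9.0)
    )
    shapes.append(
        _Shape(kind="text", cls="legend-tick", points=[(x + w, y + h + 11)],
               text="100", fill="#000000", anchor="end", size=9.0)
    )
    return shapes


def _build_geometry(
    features: pd.DataFrame,
    colours: pd.DataFrame,
    links: Sequence[CrossLink],
    selection: SequenceSelection,
    config: PlotConfig,
) -> _Geometry:
    sel_ids = selection.genome_ids
    lengths: dict[str, int] = {}
    for g in sel_ids:
        sub = features[features["genome_id"] == g]
        if sub.empty:
            raise ValueError(f"selected genome {g} has no features")
        lengths[g] = int(sub["end"].max())
    colour_map = {
        (r.genome_id, r.key): r.colour for r in colours.itertuples(index=False)
    }
    max_len = max(lengths.values())
    scale = config.scale if config.scale else max_len / _PLOT_W  # bp per unit
    width = _MARGIN_L + max_len / scale + _MARGIN_R
    height = _HEADER_H + len(sel_ids) * (_TRACK_H + _TRACK_GAP)

    def draw_interval(g: str, s: int, e: int, strand: str) -> tuple[float, float, str]:
        """Track-local x extent and effective strand after orientation."""
        if selection.orientation(g) == "reverse":
            L = lengths[g]
            s, e = L - e, L - s
            strand = "-" if strand == "+" else "+"
        return _MARGIN_L + s / scale, _MARGIN_L + e / scale, strand

    track_y = {
        g: _HEADER_H + i * (_TRACK_H + _TRACK_GAP) + _TRACK_H / 2.0
        for i, g in enumerate(sel_ids)
    }

    gene_extent: dict[tuple[str, str], tuple[float, float]] = {}
    tracks: list[tuple[str, list[_Shape]]] = []
    for g in sel_ids:
        y = track_y[g]
        shapes: list[_Shape] = [
            _Shape(kind="text", cls="track-label", points=[(8.0, y + 4.0)], text=g,
                   fill="#000000"),
            _Shape(
                kind="line",
                cls="backbone",
                points=[(_MARGIN_L, y), (_MARGIN_L + lengths[g] / scale, y)],
                stroke="#666666",
            ),
        ]
        sub = features[features["genome_id"] == g].sort_values(
            ["start", "key"], kind="mergesort"
        )
        for row in sub.itertuples(index=False):
            x1, x2, strand = draw_interval(g, int(row.start), int(row.end), row.strand)
            gene_extent[(g, row.key)] = (x1, x2)
            fill = colour_map.get((g, row.key))
            if fill is None:
                raise ValueError(f"no colour for plotted gene {g}:{row.key}")
            shapes.append(
                _Shape(
                    kind="polygon",
                    cls="gene",
                    points=_gene_polygon(x1, x2, y, strand, config.gene_shape),
                    fill=fill,
                    stroke="#333333",
                )
            )
        tracks.append((g, shapes))

    link_shapes: list[_Shape] = []
    for ln in links:
        ux = gene_extent.get((ln.upper_genome, ln.upper_key))
        lx = gene_extent.get((ln.lower_genome, ln.lower_key))
        if ux is None or lx is None:
            continue
        y1 = track_y[ln.upper_genome] + _TRACK_H / 2.0
        y2 = track_y[ln.lower_genome] - _TRACK_H / 2.0
        link_shapes.append(
            _Shape(
                kind="polygon",
                cls="link",
                points=[(ux[0], y1), (ux[1], y1), (lx[1], y2), (lx[0], y2)],
                fill=colour_for_identity(ln.percent_identity, config.identity_stops),
                opacity=0.55,
            )
        )

    deco: list[_Shape] = [
        _Shape(kind="text", cls="title", points=[(width / 2.0, 28.0)],
               text=config.title, fill="#000000", anchor="middle", size=16.0)
    ]
    bar_w = 180.0
    deco += _legend_bar(_MARGIN_L, 58.0, bar_w, 10.0, config.identity_stops,
                        "% identity (cross-links)")
    deco += _legend_bar(_MARGIN_L + bar_w + 60.0, 58.0, bar_w, 10.0,
                        config.palette_stops, "% conservation (genes)")
    return _Geometry(width=width, height=height, title=config.title,
                     tracks=tracks, links=link_shapes, decorations=deco)


# ------------------------------------------------------------ SVG backend


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _shape_svg(s: _Shape) -> str:
    if s.kind == "polygon":
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in s.points)
        op = f' fill-opacity="{s.opacity:.2f}"' if s.opacity != 1.0 else ""
        return (
            f'<polygon class="{s.cls}" points="{pts}" fill="{s.fill}" '
            f'stroke="{s.stroke}"{op}/>'
        )
    if s.kind == "rect":
        (x1, y1), (x2, y2) = s.points
        return (
            f'<rect class="{s.cls}" x="{_fmt(x1)}" y="{_fmt(y1)}" '
            f'width="{_fmt(x2 - x1)}" height="{_fmt(y2 - y1)}" fill="{s.fill}"/>'
        )
    if s.kind == "line":
        (x1, y1), (x2, y2) = s.points
        return (
            f'<line class="{s.cls}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="{s.stroke}"/>'
        )
    (x, y) = s.points[0]
    return (
        f'<text class="{s.cls}" x="{_fmt(x)}" y="{_fmt(y)}" '
        f'font-size="{s.size:.1f}" font-family="Helvetica,Arial,sans-serif" '
        f'text-anchor="{s.anchor}" fill="{s.fill}">{_xml_escape(s.text)}</text>'
    )


def _geometry_to_svg(geo: _Geometry) -> str:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(geo.width)}" '
        f'height="{_fmt(geo.height)}" '
        f'viewBox="0 0 {_fmt(geo.width)} {_fmt(geo.height)}">',
        f"<title>{_xml_escape(geo.title)}</title>",
        '<rect class="background" x="0" y="0" width="100%" height="100%" fill="#FFFFFF"/>',
        '<g class="decorations">',
        *(_shape_svg(s) for s in geo.decorations),
        "</g>",
        '<g class="links">',
        *(_shape_svg(s) for s in geo.links),
        "</g>",
    ]
    for genome_id, shapes in geo.tracks:
        lines.append(f'<g class="track" id="track-{_xml_escape(genome_id)}">')
        lines.extend(_shape_svg(s) for s in shapes)
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------ PNG backend


def _geometry_to_png(geo: _Geometry, path: Path, dpi: int) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon, Rectangle

    fig, ax = plt.subplots(figsize=(geo.width / 96.0, geo.height / 96.0))
    ax.set_xlim(0, geo.width)
    ax.set_ylim(geo.height, 0)  # SVG y-down convention
    ax.axis("off")
    anchor_map = {"start": "left", "middle": "center", "end": "right"}

    def draw(s: _Shape) -> None:
        if s.kind == "polygon":
            ax.add_patch(
                MplPolygon(
                    s.points,
                    closed=True,
                    facecolor=s.fill,
                    edgecolor=None if s.stroke == "none" else s.stroke,
                    alpha=s.opacity,
                    linewidth=0.6,
                )
            )
        elif s.kind == "rect":
            (x1, y1), (x2, y2) = s.points
            ax.add_patch(Rectangle((x1, y1), x2 - x1, y2 - y1, facecolor=s.fill))
        elif s.kind == "line":
            (x1, y1), (x2, y2) = s.points
            ax.plot([x1, x2], [y1, y2], color=s.stroke, linewidth=0.8)
        else:
            (x, y) = s.points[0]
            ax.text(x, y, s.text, fontsize=s.size * 0.75, color=s.fill,
                    ha=anchor_map[s.anchor], va="baseline")

    for s in geo.decorations:
        draw(s)
    for s in geo.links:
        draw(s)
    for _, shapes in geo.tracks:
        for s in shapes:
            draw(s)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render_synteny(
    features: pd.DataFrame,
    colours: pd.DataFrame,
    links: Sequence[CrossLink],
    selection: SequenceSelection,
    config: PlotConfig,
    out_prefix: str | Path,
) -> list[Path]:
    """Render the diagram to ``<out_prefix>.svg`` / ``.png``.

    Zero links is not an error; the tracks still render.  Identical
    inputs and config produce byte-identical SVG.
    """
    sub = features[features["genome_id"].isin(selection.genome_ids)]
    geo = _build_geometry(sub, colours, links, selection, config)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    svg_text = _geometry_to_svg(geo)
    if "svg" in config.output_formats:
        svg_path = out_prefix.with_suffix(".svg")
        svg_path.write_text(svg_text)
        written.append(svg_path)
    if "png" in config.output_formats:
        png_path = out_prefix.with_suffix(".png")
        _geometry_to_png(geo, png_path, config.dpi)
        written.append(png_path)
    return written


def plot_job(
    data_dir: str | Path,
    selection_csv: str | Path,
    mode: Literal["blastn", "blastp"] = "blastn",
    config: Optional[PlotConfig] = None,
    out_name: Optional[str] = None,
) -> dict[str, Path]:
    """Create one plot (and its colour table) from existing artifacts.

    Reads only: the processed feature table, the mode's best-hit
    summary and uniqueness tables.  Writes only into ``plots/``: the
    diagram files and the per-plot ``colour_table.parquet``.  Upstream
    tables are never touched, so re-plotting with a new selection or
    style needs no recomputation.
    """
    config = config or PlotConfig()
    ws = Workspace(data_dir)
    selection = read_selection_csv(selection_csv)
    if len(selection) < 2:
        raise ValueError("selection needs at least 2 genomes for plotting")
    features = ws.read_table(artifacts.PROCESSED_DF, step_hint="validate")
    summary = ws.read_table(
        artifacts.SUMMARY_FOR_MODE[mode], step_hint=mode
    )
    uniq = ws.read_table(artifacts.UNIQUENESS_FOR_MODE[mode], step_hint=mode)
    colours = compute_colour_table(uniq, selection, config.palette)
    links = compute_cross_links(summary, selection, config.min_link_identity)
    name = out_name or "synteny"
    plot_dir = ws.plots_dir / name
    plot_dir.mkdir(parents=True, exist_ok=True)
    files = render_synteny(
        features, colours, links, selection, config, plot_dir / name
    )
    colour_path = plot_dir / artifacts.COLOUR_TABLE
    colours.to_parquet(colour_path, index=False)
    return {
        "plots": files,  # type: ignore[dict-item]
        "colour_table": colour_path,
    }
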