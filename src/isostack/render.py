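"""Figure layout and output: read stacks on the compressed axis.

The layout stage is pure computation: it turns ordered clusters, the
coordinate map, alternative-exon calls and mismatch sites into a
:class:`PlotSpec` of rectangles, connector lines and dots in plot
coordinates, one row per read, stacked by cluster within each cell type,
with the annotation transcripts at the bottom. Rendering is then a dumb
translation of the spec to matplotlib (PDF/SVG/PNG) or to a standalone
HTML page embedding an SVG with native hover tooltips.

Fixed feature colors (user-overridable): SNV dots blue, insertion dots
green, deletion dots red, alternative exons orange. Cell types cycle
through a categorical palette.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .altexons import AltExonCall
from .cluster import IsoformCluster, order_reads_within_cluster
from .compress import CoordinateMap
from .mismatch import DELETION, INSERTION, SNV, MismatchObservation, MismatchSite
from .model import GeneAnnotation, ParameterError

FEATURE_COLORS = {
    SNV: "#1f77dd",        # blue
    INSERTION: "#2ca02c",  # green
    DELETION: "#d62728",   # red
    "alt_exon": "#ff8c00", # orange
    "annotation": "#222222",
}

CELL_TYPE_PALETTE = (
    "#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
    "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd",
)


@dataclass(frozen=True)
class Rect:
    x0: float
    x1: float
    row: int
    color: str
    role: str  # "exon" | "alt_exon" | "annotation"


@dataclass(frozen=True)
class Line:
    x0: float
    x1: float
    row: int


@dataclass(frozen=True)
class Dot:
    x: float
    row: int
    kind: str
    freq_pct: float


@dataclass(frozen=True)
class RowInfo:
    row: int
    read_id: str
    cell_type: str
    cluster_size: int


@dataclass
class PlotSpec:
    """Everything a renderer needs, already in plot coordinates."""

    axis_length: float
    tracks: list[tuple[str, list[RowInfo]]]  # (cell_type, its rows)
    rects: list[Rect] = field(default_factory=list)
    lines: list[Line] = field(default_factory=list)
    dots: list[Dot] = field(default_factory=list)
    annotation_rows: list[tuple[str, int]] = field(default_factory=list)
    palette: dict[str, str] = field(default_factory=dict)
    n_rows: int = 0
    title: str = ""

    @property
    def width_height(self) -> tuple[float, float]:
        """Figure size in inches: width fixed by axis, height by row count."""
        return (
            max(6.0, min(16.0, self.axis_length / 300.0)),
            1.5 + 0.045 * self.n_rows,
        )


def _carve_exon(
    x0: float, x1: float, alt_boxes: list[tuple[float, float]], color: str, row: int,
    subinterval_recolor: bool,
) -> list[Rect]:
    """Split one exon rectangle around contained alternative-exon boxes.

    A block exactly matching a flagged exon is drawn whole in the
    alternative color; a larger (retained-intron) block keeps the cell
    color with only the matching sub-interval recolored, unless
    sub-interval recoloring is disabled.
    """
    eps = 1e-6
    for a, b in alt_boxes:
        if abs(a - x0) < eps and abs(b - x1) < eps:
            return [Rect(x0, x1, row, FEATURE_COLORS["alt_exon"], "alt_exon")]
    if not subinterval_recolor:
        return [Rect(x0, x1, row, color, "exon")]
    inside = sorted((a, b) for a, b in alt_boxes if a >= x0 - eps and b <= x1 + eps)
    if not inside:
        return [Rect(x0, x1, row, color, "exon")]
    rects = []
    cursor = x0
    for a, b in inside:
        if a > cursor + eps:
            rects.append(Rect(cursor, a, row, color, "exon"))
        rects.append(Rect(a, b, row, FEATURE_COLORS["alt_exon"], "alt_exon"))
        cursor = b
    if cursor < x1 - eps:
        rects.append(Rect(cursor, x1, row, color, "exon"))
    return rects


def compute_layout(
    clusters_by_celltype: Sequence[tuple[str, Sequence[IsoformCluster]]],
    cmap: CoordinateMap,
    alt_calls: Sequence[AltExonCall] = (),
    sites: Sequence[MismatchSite] = (),
    annotation: Optional[GeneAnnotation] = None,
    observations: Sequence[MismatchObservation] = (),
    palette: Optional[dict[str, str]] = None,
    subinterval_recolor: bool = True,
    title: str = "",
) -> PlotSpec:
    """Assemble the figure layout.

    One row per read, rows contiguous per cell type in the given order
    and already-ordered clusters. Passing mismatch sites become dots: on
    every read row carrying the observation when per-read observations
    are supplied, else on a per-site summary row above the stacks.
    Annotation transcripts overlapping the read-covered span are drawn
    (unclipped) at the bottom.
    """
    if not clusters_by_celltype or all(not cs for _, cs in clusters_by_celltype):
        raise ParameterError("nothing to plot: no clusters supplied")

    palette = dict(palette or {})
    for i, (ct, _) in enumerate(clusters_by_celltype):
        palette.setdefault(ct, CELL_TYPE_PALETTE[i % len(CELL_TYPE_PALETTE)])

    flagged_boxes = [
        cmap.to_plot_interval(c.exon) for c in alt_calls if c.is_alternative
    ]
    passing = [s for s in sites if s.passes]
    passing_keys = {(s.ref_pos, s.kind, s.ref_allele, s.alt_allele) for s in passing}
    obs_by_read: dict[str, list[MismatchObservation]] = {}
    for o in observations:
        if (o.ref_pos, o.kind, o.ref_allele, o.alt_allele) in passing_keys:
            obs_by_read.setdefault(o.read_id, []).append(o)

    spec = PlotSpec(axis_length=cmap.total_plot_length, tracks=[], palette=palette,
                    title=title)
    row = 0
    covered_lo, covered_hi = None, None
    for ct, clusters in clusters_by_celltype:
        rows_here: list[RowInfo] = []
        for cluster in clusters:
            for read in order_reads_within_cluster(cluster):
                span = read.span
                covered_lo = span.start if covered_lo is None else min(covered_lo, span.start)
                covered_hi = span.end if covered_hi is None else max(covered_hi, span.end)
                x_first = cmap.to_plot(span.start)
                x_last = cmap.to_plot(span.end)
                spec.lines.append(Line(x_first, x_last, row))
                for exon in read.exons:
                    x0, x1 = cmap.to_plot_interval(exon)
                    spec.rects.extend(
                        _carve_exon(x0, x1, flagged_boxes, palette[ct], row,
                                    subinterval_recolor)
                    )
                for o in obs_by_read.get(read.read_id, ()):
                    site = next(
                        s for s in passing
                        if (s.ref_pos, s.kind, s.ref_allele, s.alt_allele)
                        == (o.ref_pos, o.kind, o.ref_allele, o.alt_allele)
                    )
                    spec.dots.append(
                        Dot(cmap.to_plot(o.ref_pos), row, o.kind, site.freq_pct)
                    )
                rows_here.append(RowInfo(row, read.read_id, ct, cluster.size))
                row += 1
        if rows_here:
            spec.tracks.append((ct, rows_here))

    if not observations:
        # per-site summary placement: one dot per passing site on row -1
        for s in passing:
            spec.dots.append(Dot(cmap.to_plot(s.ref_pos), -1, s.kind, s.freq_pct))

    if annotation is not None and covered_lo is not None:
        for tx_id, exons in annotation.transcripts:
            if exons[-1].end <= covered_lo or exons[0].start >= covered_hi:
                continue  # transcript outside the read-covered span
            spec.annotation_rows.append((tx_id, row))
            x_first = cmap.to_plot(exons[0].start)
            x_last = cmap.to_plot(exons[-1].end)
            spec.lines.append(Line(x_first, x_last, row))
            for exon in exons:
                x0, x1 = cmap.to_plot_interval(exon)
                spec.rects.append(
                    Rect(x0, x1, row, FEATURE_COLORS["annotation"], "annotation")
                )
            row += 1

    spec.n_rows = row
    for r in spec.rects:
        assert 0 <= r.x0 <= r.x1 <= spec.axis_length + 1e-6
    return spec


# ---------------------------------------------------------------------------
# static rendering (matplotlib)
# ---------------------------------------------------------------------------


def render_static(spec: PlotSpec, path: str, format: Optional[str] = None) -> None:
    """Write the figure as PDF, SVG or PNG.

    Every exon rectangle and mismatch dot carries a stable SVG element
    id (``exon-rect-*``, ``alt-rect-*``, ``ann-rect-*``, ``mm-dot-*``),
    so rendered glyph counts can be checked structurally.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("pdf", "svg", "png"):
        raise ParameterError(f"unknown format {fmt!r}; choose pdf, svg or png")

    w, h = spec.width_height
    fig, ax = plt.subplots(figsize=(w, h))
    row_h = 0.72
    for i, line in enumerate(spec.lines):
        ax.plot(
            [line.x0, line.x1], [-line.row, -line.row],
            color="#999999", lw=0.6, zorder=1, gid=f"intron-line-{i}",
        )
    counters = {"exon": 0, "alt_exon": 0, "annotation": 0}
    gid_prefix = {"exon": "exon-rect", "alt_exon": "alt-rect", "annotation": "ann-rect"}
    for r in spec.rects:
        i = counters[r.role]
        counters[r.role] += 1
        ax.add_patch(
            Rectangle(
                (r.x0, -r.row - row_h / 2), r.x1 - r.x0, row_h,
                facecolor=r.color, edgecolor="none", zorder=2,
                gid=f"{gid_prefix[r.role]}-{i}",
            )
        )
    for i, d in enumerate(spec.dots):
        ax.plot(
            [d.x], [-d.row], marker="o", ms=2.5, mew=0,
            color=FEATURE_COLORS[d.kind], zorder=3, gid=f"mm-dot-{i}",
        )
    # cell-type section labels at the left margin
    for ct, rows in spec.tracks:
        mid = sum(r.row for r in rows) / len(rows)
        ax.text(
            -0.01 * spec.axis_length, -mid, ct, ha="right", va="center",
            fontsize=7, color=spec.palette.get(ct, "#000000"),
        )
    for tx_id, row in spec.annotation_rows:
        ax.text(
            -0.01 * spec.axis_length, -row, tx_id, ha="right", va="center",
            fontsize=6, color=FEATURE_COLORS["annotation"],
        )
    ax.set_xlim(-0.12 * spec.axis_length, spec.axis_length * 1.01)
    ax.set_ylim(-spec.n_rows - 1, 2)
    ax.axis("off")
    if spec.title:
        ax.set_title(spec.title, fontsize=10)
    fig.savefig(path, format=fmt, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# interactive rendering (standalone HTML, no external dependencies)
# ---------------------------------------------------------------------------


def render_interactive(spec: PlotSpec, path: str) -> None:
    """Write a standalone HTML page with hover tooltips.

    The page embeds one SVG, one ``<g class="trace">`` group per cell
    type (plus one for the annotation); every glyph carries a ``<title>``
    child, which browsers show as a native hover tooltip: read id, cell
    type and cluster size for exon rectangles; kind and frequency for
    mismatch dots.
    """
    row_h = 10.0
    pad_left = 120.0
    scale_x = max(0.2, min(2.0, 1200.0 / max(spec.axis_length, 1.0)))
    width = pad_left + spec.axis_length * scale_x + 20
    height = (spec.n_rows + 3) * row_h + 40

    def X(x: float) -> float:
        return pad_left + x * scale_x

    def Y(row: int) -> float:
        return 25 + (row + 1) * row_h

    info_by_row = {ri.row: ri for _, rows in spec.tracks for ri in rows}
    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" font-family="sans-serif">'
    )
    for line in spec.lines:
        parts.append(
            f'<line x1="{X(line.x0):.2f}" x2="{X(line.x1):.2f}" '
            f'y1="{Y(line.row):.2f}" y2="{Y(line.row):.2f}" '
            'stroke="#999999" stroke-width="0.6"/>'
        )
    ann_parts: list[str] = []
    trace_parts: dict[str, list[str]] = {ct: [] for ct, _ in spec.tracks}
    for r in spec.rects:
        ri = info_by_row.get(r.row)
        y = Y(r.row)
        rect = (
            f'<rect x="{X(r.x0):.2f}" y="{y - 0.4 * row_h:.2f}" '
            f'width="{max((r.x1 - r.x0) * scale_x, 0.5):.2f}" height="{0.8 * row_h:.2f}" '
            f'fill="{r.color}">'
        )
        if r.role == "annotation" or ri is None:
            ann_parts.append(rect + "<title>annotation</title></rect>")
        else:
            tip = html.escape(
                f"read {ri.read_id} | cell type {ri.cell_type} | "
                f"cluster size {ri.cluster_size}"
                + (" | alternative exon" if r.role == "alt_exon" else "")
            )
            trace_parts[ri.cell_type].append(rect + f"<title>{tip}</title></rect>")
    for ct, body in trace_parts.items():
        label_y = Y(min(ri.row for _, rows in spec.tracks for ri in rows if ri.cell_type == ct))
        parts.append(f'<g class="trace" id="trace-{html.escape(ct)}">')
        parts.append(
            f'<text x="5" y="{label_y:.2f}" font-size="9" '
            f'fill="{spec.palette.get(ct, "#000")}">{html.escape(ct)}</text>'
        )
        parts.extend(body)
        parts.append("</g>")
    if ann_parts:
        parts.append('<g class="trace" id="trace-annotation">')
        parts.extend(ann_parts)
        parts.append("</g>")
    for d in spec.dots:
        tip = html.escape(f"{d.kind} | frequency {d.freq_pct:.2f}%")
        parts.append(
            f'<circle cx="{X(d.x):.2f}" cy="{Y(d.row):.2f}" r="2" '
            f'fill="{FEATURE_COLORS[d.kind]}"><title>{tip}</title></circle>'
        )
    parts.append("</svg>")
    title = html.escape(spec.title or "isoform read stacks")
    with open(path, "w") as fh:
        fh.write(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{title}</title></head><body>"
            f"<h3>{title}</h3>" + "".join(parts) + "</body></html>"
        )
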