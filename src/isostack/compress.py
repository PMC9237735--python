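"""Exon-preserving coordinate compression.

Long-read isoform plots must show exons separated by introns up to ~100x
their size. The transform built here keeps every exon-bearing region at
real scale and shrinks each maximal exon-free gap to a fixed plot width
(default 100 bases). Gaps already at or below that width stay at real
scale, so compression never enlarges.

"Exon-bearing" is judged against the union of ALL exonic evidence given
to :func:`build_coordinate_map` — annotation exons plus every read's exon
blocks — so an intron retained in even one read keeps that region at real
scale. A consequence (documented behavior, not a bug) is that short
retained introns are drawn to scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .model import GenomicInterval, merge_intervals

DEFAULT_COMPRESSED_WIDTH = 100


@dataclass(frozen=True)
class Segment:
    """One piece of the piecewise transform."""

    genomic: GenomicInterval
    plot_start: float
    plot_length: float

    @property
    def compressed(self) -> bool:
        return self.plot_length < len(self.genomic)

    @property
    def plot_end(self) -> float:
        return self.plot_start + self.plot_length


@dataclass(frozen=True)
class CoordinateMap:
    """Piecewise monotonic genomic -> plot-axis transform.

    Segments tile the span without gaps or overlaps; real-scale segments
    are isometries (shift only), compressed segments interpolate linearly
    onto ``compressed_width`` plot bases.
    """

    span: GenomicInterval
    segments: tuple[Segment, ...]
    compressed_width: int

    @property
    def total_plot_length(self) -> float:
        return self.segments[-1].plot_end

    def to_plot(self, pos: int | float) -> float:
        """Map a genomic position onto the plot axis.

        Exact shift inside real-scale segments; linear interpolation
        inside compressed ones. Monotonically non-decreasing overall.
        """
        if not (self.span.start <= pos <= self.span.end):
            raise ValueError(
                f"position {pos} outside span [{self.span.start}, {self.span.end}]"
            )
        if pos == self.span.end:
            return self.total_plot_length
        for seg in self.segments:
            if seg.genomic.start <= pos < seg.genomic.end:
                frac = (pos - seg.genomic.start) / len(seg.genomic)
                return seg.plot_start + frac * seg.plot_length
        raise AssertionError("segments do not tile the span")  # pragma: no cover

    def to_plot_interval(self, iv: GenomicInterval) -> tuple[float, float]:
        """Map an interval; never empty for a non-empty input."""
        a, b = self.to_plot(iv.start), self.to_plot(iv.end)
        return (a, max(b, a + 1e-9))

    def export_table(self, path: str) -> None:
        """Debug dump: genomic_start, genomic_end, plot_start per segment."""
        with open(path, "w") as fh:
            fh.write("genomic_start\tgenomic_end\tplot_start\n")
            for seg in self.segments:
                fh.write(
                    f"{seg.genomic.start}\t{seg.genomic.end}\t{seg.plot_start:g}\n"
                )


def build_coordinate_map(
    exonic_intervals: Sequence[GenomicInterval],
    span: GenomicInterval,
    compressed_width: int = DEFAULT_COMPRESSED_WIDTH,
) -> CoordinateMap:
    """Build the transform from pooled exonic evidence over ``span``.

    Parameters
    ----------
    exonic_intervals:
        Every exon interval from the annotation and from the reads.
        Overlaps are unioned; maximal exon-free gaps between union blocks
        (including flanks before the first and after the last block)
        become compressed segments.
    span:
        The full genomic region being plotted.
    compressed_width:
        Plot width (bases) for each exon-free gap longer than this value;
        shorter gaps keep their genomic length.
    """
    if compressed_width < 1:
        raise ValueError(f"compressed_width must be >= 1, got {compressed_width}")
    for iv in exonic_intervals:
        if not span.contains(iv):
            raise ValueError(f"exonic interval {iv} outside span {span}")

    blocks = merge_intervals(list(exonic_intervals))
    if not blocks:
        warnings.warn(
            "no exonic intervals supplied; whole span kept at real scale",
            stacklevel=2,
        )
        blocks = [GenomicInterval(span.chrom, span.start, span.end)]

    # Alternate gap/exon pieces tiling the span; gaps of length 0 dropped.
    pieces: list[tuple[GenomicInterval, bool]] = []  # (interval, is_exonic)
    cursor = span.start
    for b in blocks:
        if b.start > cursor:
            pieces.append((GenomicInterval(span.chrom, cursor, b.start), False))
        pieces.append((GenomicInterval(span.chrom, b.start, b.end), True))
        cursor = b.end
    if cursor < span.end:
        pieces.append((GenomicInterval(span.chrom, cursor, span.end), False))

    segments: list[Segment] = []
    plot_cursor = 0.0
    for iv, is_exonic in pieces:
        glen = len(iv)
        plen = float(glen) if is_exonic else float(min(glen, compressed_width))
        segments.append(Segment(iv, plot_cursor, plen))
        plot_cursor += plen

    return CoordinateMap(span=span, segments=tuple(segments), compressed_width=compressed_width)
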