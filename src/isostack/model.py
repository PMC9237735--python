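"""Core domain types shared by every stage of the pipeline.

All coordinates inside the package are 0-based half-open ``[start, end)``
on a single chromosome. Format dialects that use other conventions
(GTF/GFF: 1-based inclusive) are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


class IsostackError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IsostackError):
    """Malformed input file (bad column count, bad coordinates, duplicates)."""


class LookupError_(IsostackError):
    """Requested record (e.g. a gene id) absent from the input."""


class ParameterError(IsostackError):
    """Invalid user-supplied parameter (window bounds, margins, formats)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    strand is "+", "-" or "." (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class ReadIsoform:
    """One long read: its exon blocks plus per-read metadata.

    Exons are sorted, non-overlapping and separated by at least one base
    (book-ended blocks must be merged upstream). ``tss``/``polya`` are
    optional positions assigned by the upstream single-cell pipeline and
    are consumed as given.
    """

    read_id: str
    exons: Sequence[GenomicInterval]
    gene_id: str = ""
    cell_type: str = ""
    barcode: Optional[str] = None
    tss: Optional[int] = None
    polya: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"read {self.read_id}: needs at least one exon")
        self.exons = tuple(self.exons)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"read {self.read_id}: exons on multiple chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"read {self.read_id}: exons must be strictly increasing "
                    f"with a gap of >=1 base ({a} then {b})"
                )
        span = self.span
        for label, pos in (("tss", self.tss), ("polya", self.polya)):
            if pos is not None and not (span.start <= pos <= span.end):
                raise ValueError(
                    f"read {self.read_id}: {label}={pos} outside span "
                    f"[{span.start}, {span.end}]"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint: first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneAnnotation:
    """Reference gene model: span plus per-transcript exon lists."""

    gene_id: str
    gene_name: str
    span: GenomicInterval
    transcripts: list[tuple[str, list[GenomicInterval]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tx_id, exons in self.transcripts:
            exons.sort(key=lambda e: (e.start, e.end))
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ValueError(f"transcript {tx_id}: overlapping exons")
            for e in exons:
                if not self.span.contains(e):
                    raise ValueError(f"transcript {tx_id}: exon {e} outside gene span")

    @property
    def exons(self) -> list[GenomicInterval]:
        """All transcript exons (with duplicates across transcripts)."""
        return [e for _, exs in self.transcripts for e in exs]


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sort and merge overlapping or book-ended blocks."""
    if not intervals:
        return []
    chrom = intervals[0].chrom
    ivs = sorted(intervals, key=lambda e: (e.start, e.end))
    merged: list[tuple[int, int]] = []
    for iv in ivs:
        if iv.chrom != chrom:
            raise ValueError("cannot merge intervals on different chromosomes")
        if merged and iv.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
        else:
            merged.append((iv.start, iv.end))
    return [GenomicInterval(chrom, s, e) for s, e in merged]
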