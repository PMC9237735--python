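"""Alternative-exon calling by percent spliced in (Psi).

For each candidate exon, Psi is the fraction of overlapping reads that
include it, pooled across ALL cell types. A read *overlaps* the exon when
its genomic footprint (first exon start to last exon end) intersects it
by at least one base — so a read that splices the exon out still counts
in the denominator, which is what makes Psi an inclusion fraction. A read
*includes* the exon when one of its exon blocks fully contains the
candidate interval; a retained-intron block containing the exon region
therefore counts as inclusion.

An exon is flagged alternative when 100*Psi lies inside a closed window,
[5, 95] by default. For higher-error chemistries (Oxford Nanopore) a
narrower [20, 80] window gives a clearer picture and is available as the
ONT preset. Exons included by every overlapping read (constitutive) or by
none fall outside any such window and are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .model import GenomicInterval, GeneAnnotation, ParameterError, ReadIsoform

DEFAULT_LOWER_PCT = 5.0
DEFAULT_UPPER_PCT = 95.0
ONT_LOWER_PCT = 20.0
ONT_UPPER_PCT = 80.0


@dataclass(frozen=True)
class AltExonCall:
    """Inclusion statistics for one candidate exon interval."""

    exon: GenomicInterval
    included: int
    overlapping: int
    psi: Optional[float]  # None when overlapping == 0
    is_alternative: bool
    lower_pct: float = DEFAULT_LOWER_PCT
    upper_pct: float = DEFAULT_UPPER_PCT


def _check_window(lower_pct: float, upper_pct: float) -> None:
    if not (0 <= lower_pct <= upper_pct <= 100):
        raise ParameterError(
            f"need 0 <= lower <= upper <= 100, got ({lower_pct}, {upper_pct})"
        )


def enumerate_candidate_exons(
    reads: Iterable[ReadIsoform], annotation: Optional[GeneAnnotation] = None
) -> list[GenomicInterval]:
    """Unique exon intervals pooled from annotation transcripts and reads.

    The candidate unit is the exact (start, end) variant: overlapping
    variants with different boundaries are scored independently. Novel
    read-only exons are candidates alongside annotated ones.
    """
    seen: set[tuple[int, int]] = set()
    chrom = None
    for read in reads:
        chrom = chrom or read.chrom
        for e in read.exons:
            seen.add((e.start, e.end))
    if annotation is not None:
        chrom = chrom or annotation.span.chrom
        for e in annotation.exons:
            seen.add((e.start, e.end))
    if chrom is None:
        return []
    return [GenomicInterval(chrom, s, e) for s, e in sorted(seen)]


def compute_inclusion(
    exon: GenomicInterval,
    reads: Sequence[ReadIsoform],
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> AltExonCall:
    """Count overlapping/including reads for one exon and compute Psi.

    ``reads`` must be pooled across all cell types.
    """
    _check_window(lower_pct, upper_pct)
    overlapping = 0
    included = 0
    for read in reads:
        if not read.span.overlaps(exon):
            continue
        overlapping += 1
        if any(block.contains(exon) for block in read.exons):
            included += 1
    if overlapping == 0:
        return AltExonCall(exon, 0, 0, None, False, lower_pct, upper_pct)
    psi = included / overlapping
    is_alt = lower_pct <= 100.0 * psi <= upper_pct
    return AltExonCall(exon, included, overlapping, psi, is_alt, lower_pct, upper_pct)


def call_alt_exons(
    reads: Sequence[ReadIsoform],
    annotation: Optional[GeneAnnotation] = None,
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> list[AltExonCall]:
    """Enumerate candidates and score each one. Convenience wrapper."""
    return [
        compute_inclusion(exon, reads, lower_pct, upper_pct)
        for exon in enumerate_candidate_exons(reads, annotation)
    ]


def flag_alternative(
    calls: Iterable[AltExonCall],
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> list[AltExonCall]:
    """Re-flag calls under a new closed window; counts untouched.

    Both boundaries are inclusive ("at least ... at most"). Widening the
    window never unflags an exon.
    """
    _check_window(lower_pct, upper_pct)
    out = []
    for call in calls:
        is_alt = (
            call.psi is not None and lower_pct <= 100.0 * call.psi <= upper_pct
        )
        out.append(
            replace(call, is_alternative=is_alt, lower_pct=lower_pct, upper_pct=upper_pct)
        )
    return out


def write_alt_exon_table(calls: Sequence[AltExonCall], path: str) -> None:
    """Tab-delimited export: chrom, start, end, included, overlapping, psi, flag."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tincluded\toverlapping\tpsi\tis_alternative\n")
        for c in calls:
            psi = "NA" if c.psi is None else f"{c.psi:.6g}"
            fh.write(
                f"{c.exon.chrom}\t{c.exon.start}\t{c.exon.end}\t"
                f"{c.included}\t{c.overlapping}\t{psi}\t{c.is_alternative}\n"
            )
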