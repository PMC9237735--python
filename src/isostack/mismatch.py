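"""Reference-mismatch finding on aligned long reads.

Aligned reads are compared base-by-base against the reference genome by
walking each alignment's CIGAR: aligned-base disagreements become SNV
observations, insertion/deletion gap operations become single indel
events keyed by position and allele string (one biological event, one
record — a 3-base deletion is one observation, not three).

Two filters separate signal from sequencing noise:

* *end exclusion*: mismatches within the first or last ``margin``
  (default 20) aligned reference bases of an alignment are dropped, as
  alignment ends are artifact-prone;
* *frequency window*: after aggregating observations to sites, only
  sites supported by at least ``lower_pct`` and at most ``upper_pct``
  (default 5/95) percent of overlapping reads pass — rare events are
  likely random sequencing error, near-100% events are likely genome
  differences rather than interesting heterogeneity. The (0, 100) window
  surfaces every disagreement.

The frequency denominator is per-site alignment coverage pooled across
all cell types, mirroring the Psi pooling for alternative exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import pysam

from .model import GenomicInterval, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_END_MARGIN = 20
DEFAULT_LOWER_PCT = 5.0
DEFAULT_UPPER_PCT = 95.0

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class MismatchObservation:
    """One mismatch event on one read.

    ``ref_pos`` is 0-based; for an insertion it is the reference position
    of the base following the insertion point. ``dist_from_start`` /
    ``dist_from_end`` are 1-based offsets of the event's anchor base from
    the alignment's reference start/end (an insertion anchors on its left
    flanking base; a deletion measures its first base from the start and
    its last base from the end).
    """

    read_id: str
    ref_pos: int
    kind: str
    ref_allele: str  # empty for insertion
    alt_allele: str  # empty for deletion
    dist_from_start: int
    dist_from_end: int


@dataclass(frozen=True)
class MismatchSite:
    """Aggregated per-site mismatch with its frequency filter status."""

    chrom: str
    ref_pos: int
    kind: str
    ref_allele: str
    alt_allele: str
    support: int
    overlapping: int
    freq_pct: float
    passes: bool


@dataclass(frozen=True)
class AlignmentSpan:
    """Reference footprint of one alignment (enough to compute coverage)."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int


def _reference_lookup(reference, chrom: str):
    """Return a callable fetch(start, end) -> uppercase sequence."""
    if isinstance(reference, str) and not set(reference.upper()) <= set("ACGTN"):
        reference = pysam.FastaFile(reference)
    if isinstance(reference, pysam.FastaFile):
        return lambda s, e: reference.fetch(chrom, s, e).upper()
    if isinstance(reference, str):  # raw chromosome sequence
        seq = reference.upper()
        return lambda s, e: seq[s:e]
    # pyfaidx.Fasta or any mapping of chrom -> sequence
    chrom_seq = str(reference[chrom]).upper()
    return lambda s, e: chrom_seq[s:e]


def _iter_alignments(alignments, region: Optional[GenomicInterval]):
    if isinstance(alignments, (str,)):
        alignments = pysam.AlignmentFile(alignments)
    if isinstance(alignments, pysam.AlignmentFile):
        if region is not None:
            try:
                yield from alignments.fetch(region.chrom, region.start, region.end)
                return
            except ValueError:  # no index (plain SAM): scan and filter
                pass
        for rec in alignments.fetch(until_eof=True):
            if region is None or (
                rec.reference_name == region.chrom
                and rec.reference_start < region.end
                and rec.reference_end is not None
                and rec.reference_end > region.start
            ):
                yield rec
    else:
        yield from alignments


def collect_observations(
    alignments: Union[str, pysam.AlignmentFile, Iterable[pysam.AlignedSegment]],
    reference,
    region: GenomicInterval,
) -> tuple[list[MismatchObservation], list[AlignmentSpan]]:
    """Walk CIGARs against the reference and record mismatch events.

    Parameters
    ----------
    alignments:
        SAM/BAM path, open AlignmentFile, or an iterable of aligned
        segments. Unmapped records and records without CIGAR or sequence
        are skipped with a logged count.
    reference:
        FASTA path, ``pysam.FastaFile``, ``pyfaidx.Fasta`` or the raw
        chromosome sequence string.
    region:
        Only events with their reference position inside this interval
        are reported (the plotted gene region).

    Returns the observations plus the reference span of every usable
    alignment overlapping the region (needed later for per-site
    coverage denominators).
    """
    fetch = _reference_lookup(reference, region.chrom)
    observations: list[MismatchObservation] = []
    spans: list[AlignmentSpan] = []
    n_skipped = 0
    for rec in _iter_alignments(alignments, region):
        if rec.is_unmapped or rec.cigartuples is None or rec.query_sequence is None:
            n_skipped += 1
            continue
        aln_start = rec.reference_start
        aln_end = rec.reference_end
        spans.append(AlignmentSpan(rec.query_name, region.chrom, aln_start, aln_end))
        ref_pos = aln_start
        q_pos = 0
        seq = rec.query_sequence.upper()

        def dists(anchor_first: int, anchor_last: int) -> tuple[int, int]:
            return (anchor_first - aln_start + 1, aln_end - anchor_last)

        for op, length in rec.cigartuples:
            if op in (0, 7, 8):  # M, =, X: aligned, compare bases
                ref_seq = fetch(ref_pos, ref_pos + length)
                for k in range(length):
                    if seq[q_pos + k] != ref_seq[k] and region.contains_pos(ref_pos + k):
                        ds, de = dists(ref_pos + k, ref_pos + k)
                        observations.append(
                            MismatchObservation(
                                rec.query_name, ref_pos + k, SNV,
                                ref_seq[k], seq[q_pos + k], ds, de,
                            )
                        )
                ref_pos += length
                q_pos += length
            elif op == 1:  # I: insertion before ref_pos
                anchor = ref_pos - 1
                if region.start <= anchor and ref_pos < region.end:
                    ds, de = dists(anchor, anchor)
                    observations.append(
                        MismatchObservation(
                            rec.query_name, ref_pos, INSERTION,
                            "", seq[q_pos : q_pos + length], ds, de,
                        )
                    )
                q_pos += length
            elif op == 2:  # D: deletion of reference bases
                if ref_pos >= region.start and ref_pos + length <= region.end:
                    ds, de = dists(ref_pos, ref_pos + length - 1)
                    observations.append(
                        MismatchObservation(
                            rec.query_name, ref_pos, DELETION,
                            fetch(ref_pos, ref_pos + length), "", ds, de,
                        )
                    )
                ref_pos += length
            elif op == 3:  # N: intron, not a mismatch event
                ref_pos += length
            elif op == 4:  # S: soft clip
                q_pos += length
            # H (5) and P (6) consume nothing relevant
    if n_skipped:
        logger.warning("skipped %d unusable alignment record(s)", n_skipped)
    return observations, spans


def apply_end_exclusion(
    obs: Iterable[MismatchObservation], margin: int = DEFAULT_END_MARGIN
) -> list[MismatchObservation]:
    """Drop observations within ``margin`` bases of either alignment end.

    ``margin=0`` is the identity; the filter is idempotent.
    """
    if margin < 0:
        raise ParameterError(f"margin must be >= 0, got {margin}")
    return [
        o for o in obs if o.dist_from_start > margin and o.dist_from_end > margin
    ]


def _site_overlaps(span: AlignmentSpan, pos: int, kind: str, ref_allele: str) -> bool:
    """Does this alignment's reference span cover the event's footprint?

    SNV: the position; deletion: the whole deleted interval; insertion:
    both flanking bases.
    """
    if kind == SNV:
        return span.ref_start <= pos < span.ref_end
    if kind == DELETION:
        return span.ref_start <= pos and pos + len(ref_allele) <= span.ref_end
    return span.ref_start <= pos - 1 and pos < span.ref_end  # insertion


def aggregate_sites(
    obs: Sequence[MismatchObservation],
    spans: Sequence[AlignmentSpan],
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> list[MismatchSite]:
    """Group (already end-filtered) observations into frequency-filtered sites.

    Observations are grouped by (position, kind, alleles); support counts
    distinct read ids; the denominator counts alignments whose reference
    span covers the event footprint. A site passes when its frequency
    lies in the closed [lower_pct, upper_pct] window.
    """
    if not (0 <= lower_pct <= upper_pct <= 100):
        raise ParameterError(
            f"need 0 <= lower <= upper <= 100, got ({lower_pct}, {upper_pct})"
        )
    grouped: dict[tuple[int, str, str, str], set[str]] = {}
    for o in obs:
        grouped.setdefault((o.ref_pos, o.kind, o.ref_allele, o.alt_allele), set()).add(
            o.read_id
        )
    chrom = spans[0].chrom if spans else "."
    sites = []
    for (pos, kind, ref_a, alt_a), read_ids in sorted(grouped.items()):
        overlapping = sum(1 for s in spans if _site_overlaps(s, pos, kind, ref_a))
        support = len(read_ids)
        freq = 100.0 * support / overlapping if overlapping else 0.0
        passes = overlapping > 0 and lower_pct <= freq <= upper_pct
        sites.append(
            MismatchSite(chrom, pos, kind, ref_a, alt_a, support, overlapping, freq, passes)
        )
    return sites


def refilter_sites(
    sites: Iterable[MismatchSite], lower_pct: float, upper_pct: float
) -> list[MismatchSite]:
    """Re-apply the frequency window without recomputing counts."""
    if not (0 <= lower_pct <= upper_pct <= 100):
        raise ParameterError(
            f"need 0 <= lower <= upper <= 100, got ({lower_pct}, {upper_pct})"
        )
    return [
        replace(s, passes=s.overlapping > 0 and lower_pct <= s.freq_pct <= upper_pct)
        for s in sites
    ]


def find_mismatches(
    alignments,
    reference,
    region: GenomicInterval,
    margin: int = DEFAULT_END_MARGIN,
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> tuple[list[MismatchSite], list[MismatchObservation]]:
    """Full pipeline: collect, end-filter, aggregate. Returns (sites, kept obs)."""
    obs, spans = collect_observations(alignments, reference, region)
    kept = apply_end_exclusion(obs, margin)
    return aggregate_sites(kept, spans, lower_pct, upper_pct), kept


def write_mismatch_table(sites: Sequence[MismatchSite], path: str) -> None:
    """Tab-delimited export: chrom, pos, kind, ref, alt, support, overlapping, freq, passes."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tkind\tref\talt\tsupport\toverlapping\tfreq_pct\tpasses\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.ref_pos}\t{s.kind}\t{s.ref_allele or '.'}\t"
                f"{s.alt_allele or '.'}\t{s.support}\t{s.overlapping}\t"
                f"{s.freq_pct:.4g}\t{s.passes}\n"
            )


def read_mismatch_table(path: str) -> list[MismatchSite]:
    """Load a table written by :func:`write_mismatch_table` (CLI cache path)."""
    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ParameterError(f"{path}: not a mismatch table")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                MismatchSite(
                    f[0], int(f[1]), f[2],
                    "" if f[3] == "." else f[3],
                    "" if f[4] == "." else f[4],
                    int(f[5]), int(f[6]), float(f[7]), f[8] == "True",
                )
            )
    return sites


def write_vcf(sites: Sequence[MismatchSite], reference, path: str) -> None:
    """Minimal VCF-like text for passing sites (anchor bases from reference)."""
    sites = [s for s in sites if s.passes]
    chrom = sites[0].chrom if sites else "."
    fetch = _reference_lookup(reference, chrom) if sites else None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            if s.kind == SNV:
                pos1, ref, alt = s.ref_pos + 1, s.ref_allele, s.alt_allele
            elif s.kind == DELETION:
                anchor = fetch(s.ref_pos - 1, s.ref_pos)
                pos1, ref, alt = s.ref_pos, anchor + s.ref_allele, anchor
            else:  # insertion
                anchor = fetch(s.ref_pos - 1, s.ref_pos)
                pos1, ref, alt = s.ref_pos, anchor, anchor + s.alt_allele
            info = f"KIND={s.kind};SUPPORT={s.support};OVERLAP={s.overlapping};FREQ={s.freq_pct:.4g}"
            fh.write(f"{s.chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
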