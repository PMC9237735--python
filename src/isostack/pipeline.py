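"""End-to-end runs: parse -> assemble -> mismatch -> compress -> cluster ->
call exons -> layout -> render -> export.

This is the programmatic equivalent of the command line: one
:class:`RunConfig` in, figures/tables plus a machine-readable run report
out. Each stage is the corresponding module's public function, so
everything here is also reachable piecemeal from Python.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import altexons, cluster, compress, io, mismatch, render
from .model import GenomicInterval, IsostackError, LookupError_, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one invocation needs.

    The Psi window (``ci_lower``/``ci_upper``) and the mismatch frequency
    window (``mm_lower``/``mm_upper``) default to 5-95%; ``end_margin``
    (20) drops mismatches near alignment ends; ``compressed_width`` (100)
    is the plot width given to each exon-free gap.
    """

    gene_id: str
    outdir: str = "isostack_out"
    input_mode: str = "allinfo"  # "allinfo" | "gff2file"
    allinfo: Optional[str] = None
    gff: Optional[str] = None
    assignments: Optional[str] = None
    annotation: Optional[str] = None
    alignments: Optional[str] = None  # SAM/BAM for mismatch finding
    fasta: Optional[str] = None
    mismatch_table: Optional[str] = None  # reuse a previous run_mismatch output
    cluster_mode: str = "chain"
    cluster_order: str = "by_size"
    cell_type_order: Optional[list[str]] = None
    ci_lower: float = altexons.DEFAULT_LOWER_PCT
    ci_upper: float = altexons.DEFAULT_UPPER_PCT
    mm_lower: float = mismatch.DEFAULT_LOWER_PCT
    mm_upper: float = mismatch.DEFAULT_UPPER_PCT
    end_margin: int = mismatch.DEFAULT_END_MARGIN
    compressed_width: int = compress.DEFAULT_COMPRESSED_WIDTH
    formats: list[str] = field(default_factory=lambda: ["pdf"])
    interactive: bool = True
    subinterval_recolor: bool = True
    palette: Optional[dict[str, str]] = None
    track_name: str = ""

    def __post_init__(self) -> None:
        if self.input_mode not in ("allinfo", "gff2file"):
            raise ParameterError(f"unknown input mode {self.input_mode!r}")
        for lo, hi, what in (
            (self.ci_lower, self.ci_upper, "Psi window"),
            (self.mm_lower, self.mm_upper, "mismatch window"),
        ):
            if not (0 <= lo <= hi <= 100):
                raise ParameterError(f"invalid {what} ({lo}, {hi})")


def _load_reads(config: RunConfig):
    if config.input_mode == "allinfo":
        if not config.allinfo:
            raise ParameterError("input mode 'allinfo' requires an AllInfo path")
        return io.parse_allinfo(config.allinfo, gene_filter=config.gene_id)
    if not (config.gff and config.assignments):
        raise ParameterError("input mode 'gff2file' requires GFF and assignment paths")
    gff_reads = io.parse_read_gff(config.gff)
    table = io.parse_assignment_table(config.assignments)
    return io.assemble_reads(gff_reads, table, gene_id=config.gene_id)


def run_mismatch(config: RunConfig) -> list[mismatch.MismatchSite]:
    """Mismatch finding alone: write the site table, return the sites.

    The table is reusable by :func:`run_plot` via ``mismatch_table``.
    An empty region yields an empty table, not an error.
    """
    if not (config.alignments and config.fasta):
        raise ParameterError("mismatch finding requires alignments and a reference FASTA")
    region = _plot_region(config)
    sites, _ = mismatch.find_mismatches(
        config.alignments, config.fasta, region,
        margin=config.end_margin,
        lower_pct=config.mm_lower, upper_pct=config.mm_upper,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / f"{config.gene_id}.mismatches.tsv"
    mismatch.write_mismatch_table(sites, str(out))
    logger.info("wrote %s (%d sites, %d passing)", out, len(sites),
                sum(s.passes for s in sites))
    return sites


def _plot_region(config: RunConfig) -> GenomicInterval:
    """Region to scan for mismatches: annotation span if given, else read span."""
    if config.annotation:
        ann = io.parse_annotation(config.annotation, config.gene_id)
        return ann.span
    reads = _load_reads(config)
    if not reads:
        raise LookupError_(f"gene {config.gene_id!r} absent from input")
    return GenomicInterval(
        reads[0].chrom,
        min(r.span.start for r in reads),
        max(r.span.end for r in reads),
        reads[0].strand,
    )


def run_plot(config: RunConfig) -> dict:
    """Full pipeline; returns the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reads = _load_reads(config)
    if not reads:
        raise LookupError_(
            f"gene {config.gene_id!r} absent from input "
            "(check the gene id against the assignment/AllInfo file)"
        )
    annotation = (
        io.parse_annotation(config.annotation, config.gene_id)
        if config.annotation
        else None
    )

    # mismatches: fresh from alignments, or a cached table
    sites: list[mismatch.MismatchSite] = []
    observations: list[mismatch.MismatchObservation] = []
    if config.alignments and config.fasta:
        span = annotation.span if annotation else _plot_region(config)
        sites, observations = mismatch.find_mismatches(
            config.alignments, config.fasta, span,
            margin=config.end_margin,
            lower_pct=config.mm_lower, upper_pct=config.mm_upper,
        )
    elif config.mismatch_table:
        sites = mismatch.read_mismatch_table(config.mismatch_table)
        sites = mismatch.refilter_sites(sites, config.mm_lower, config.mm_upper)

    # coordinate compression over all exonic evidence
    exonic = [e for r in reads for e in r.exons]
    if annotation is not None:
        exonic += annotation.exons
    lo = min(e.start for e in exonic)
    hi = max(e.end for e in exonic)
    if annotation is not None:
        lo, hi = min(lo, annotation.span.start), max(hi, annotation.span.end)
    span = GenomicInterval(reads[0].chrom, lo, hi, reads[0].strand)
    cmap = compress.build_coordinate_map(exonic, span, config.compressed_width)

    # clustering
    result = cluster.cluster_reads(reads, mode=config.cluster_mode)
    by_ct = result.by_cell_type()
    ct_order = config.cell_type_order or sorted(by_ct)
    ordered = [
        (ct, cluster.order_clusters(by_ct[ct], by=config.cluster_order))
        for ct in ct_order
        if ct in by_ct
    ]

    # alternative exons, pooled across all retained reads irrespective of cell type
    calls = altexons.call_alt_exons(
        reads, annotation, config.ci_lower, config.ci_upper
    )

    spec = render.compute_layout(
        ordered, cmap,
        alt_calls=calls, sites=sites, annotation=annotation,
        observations=observations, palette=config.palette,
        subinterval_recolor=config.subinterval_recolor,
        title=config.gene_id,
    )

    outputs = {}
    stem = outdir / config.gene_id
    for fmt in config.formats:
        out = f"{stem}.{fmt}"
        render.render_static(spec, out, fmt)
        outputs[fmt] = out
    if config.interactive:
        out = f"{stem}.html"
        render.render_interactive(spec, out)
        outputs["html"] = out
    track = f"{stem}.bed"
    io.write_ucsc_track(reads, track, config.track_name or f"{config.gene_id}_reads")
    outputs["bed"] = track
    alt_table = f"{stem}.alt_exons.tsv"
    altexons.write_alt_exon_table(calls, alt_table)
    outputs["alt_exons"] = alt_table
    if sites:
        mm_table = f"{stem}.mismatches.tsv"
        mismatch.write_mismatch_table(sites, mm_table)
        outputs["mismatches"] = mm_table
    cl_table = f"{stem}.clusters.tsv"
    with open(cl_table, "w") as fh:
        fh.write("cell_type\tcluster_rank\tsize\tchain\ttss\tpolya\n")
        for ct, clusters in ordered:
            for rank, c in enumerate(clusters, start=1):
                fh.write(
                    f"{ct}\t{rank}\t{c.size}\t{c.key.chain}\t"
                    f"{c.key.tss_bin if c.key.tss_bin is not None else '.'}\t"
                    f"{c.key.polya_bin if c.key.polya_bin is not None else '.'}\n"
                )
    outputs["clusters"] = cl_table

    report = {
        "gene_id": config.gene_id,
        "cluster_mode": config.cluster_mode,
        "reads_in": len(reads),
        "reads_retained": result.n_retained,
        "reads_excluded": result.excluded,
        "n_clusters": len(result.clusters),
        "n_cell_types": len(spec.tracks),
        "n_candidate_exons": len(calls),
        "n_alternative_exons": sum(c.is_alternative for c in calls),
        "n_mismatch_sites": len(sites),
        "n_passing_sites": sum(s.passes for s in sites),
        "plot_axis_length": spec.axis_length,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    with open(f"{stem}.report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
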