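"""Ground-truthed synthetic fixtures: toy genes, reads, alignments, reference.

Every pipeline stage is testable without external downloads: this module
builds a multi-exon toy gene with a cassette exon at controlled
per-cell-type inclusion rates, draws reads from a small isoform table at
controlled proportions, and injects substitutions, insertions and
deletions at controlled per-site frequencies. All sampling is driven by
a single integer seed through ``numpy.random.default_rng``, so output is
fully deterministic across platforms.

The same simulation is written in all input dialects the package reads —
per-read GFF + assignment table, AllInfo records, SAM alignments and the
reference FASTA — plus a truth JSON, so parsers can be checked against
one another and every measured quantity against its generating value.

What this emulates (and what it does not): full-length reads with exact
splice sites and isolated injected mismatch events. Real long reads
truncate, carry correlated base errors and wobble at splice junctions;
tests passing here demonstrate the bookkeeping is exact, not that the
method is robust to those artifacts.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .model import GeneAnnotation, GenomicInterval, ReadIsoform
from .mismatch import DELETION, INSERTION, SNV

CHROM = "chrS"
_BASES = "ACGT"
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}

DEFAULT_EXON_LENGTHS = (200, 150, 120, 90, 150, 110, 250)
DEFAULT_INTRON_LENGTHS = (1500, 10000, 800, 2500, 5000, 1200)
DEFAULT_CELL_TYPES = ("Excit", "Inhib", "Astro")
GENE_ID = "GENE1"
GENE_NAME = "Toy1"
FLANK = 200


@dataclass(frozen=True)
class InjectedSite:
    """One mismatch event class injected at a controlled frequency."""

    pos: int
    kind: str  # SNV | insertion | deletion
    length: int  # allele length (1 for SNV)
    frequency: float  # per-covering-read Bernoulli rate


@dataclass
class FixtureTruth:
    """Everything the generator decided, for use as a test oracle."""

    gene: GeneAnnotation
    genome_seq: str
    isoform_table: list[tuple[tuple[int, ...], dict[str, float]]]
    # isoform_table rows: (exon indices used, {cell_type: proportion})
    exon_inclusion_rates: dict[str, dict[int, float]]  # cell_type -> exon idx -> Psi
    injected_sites: list[InjectedSite]
    seed: int
    p_tss_missing: float = 0.0
    p_polya_missing: float = 0.0

    def __post_init__(self) -> None:
        for _, props in self.isoform_table:
            for ct in props:
                total = sum(p[ct] for _, p in self.isoform_table)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"proportions for {ct} sum to {total}, not 1")
        for site in self.injected_sites:
            if not (0.0 <= site.frequency <= 1.0):
                raise ValueError(f"injected frequency {site.frequency} outside [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.isoform_table[0][1].keys())

    @property
    def exons(self) -> list[GenomicInterval]:
        """The gene's distinct exon intervals (from the full transcript)."""
        return list(self.gene.transcripts[0][1])


@dataclass
class SimulatedDataset:
    """Simulation output: in-memory reads plus the files written."""

    truth: FixtureTruth
    reads: list[ReadIsoform]
    read_isoform_idx: dict[str, int]  # read_id -> isoform_table row
    read_events: dict[str, list[InjectedSite]]  # injected per read
    site_support: dict[int, int]  # site pos -> realized supporting reads
    paths: dict[str, Path] = field(default_factory=dict)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def make_toy_gene(
    n_exons: int = len(DEFAULT_EXON_LENGTHS),
    exon_lengths: Sequence[int] = DEFAULT_EXON_LENGTHS,
    intron_lengths: Sequence[int] = DEFAULT_INTRON_LENGTHS,
    seed: int = 0,
) -> tuple[GeneAnnotation, str]:
    """Build a toy gene annotation and its random reference sequence.

    The annotation carries a full-length transcript plus one skip-variant
    per internal exon. Deterministic for a fixed seed.
    """
    if n_exons < 2:
        raise ValueError(f"need at least 2 exons, got {n_exons}")
    if len(exon_lengths) != n_exons or len(intron_lengths) != n_exons - 1:
        raise ValueError(
            f"need {n_exons} exon lengths and {n_exons - 1} intron lengths"
        )
    if any(l < 1 for l in exon_lengths) or any(l < 1 for l in intron_lengths):
        raise ValueError("all lengths must be >= 1")
    exons = []
    pos = FLANK
    for i, elen in enumerate(exon_lengths):
        exons.append(GenomicInterval(CHROM, pos, pos + elen, "+"))
        pos += elen
        if i < n_exons - 1:
            pos += intron_lengths[i]
    span = GenomicInterval(CHROM, exons[0].start, exons[-1].end, "+")
    transcripts = [("tx_full", list(exons))]
    for i in range(1, n_exons - 1):
        transcripts.append(
            (f"tx_skip{i}", [e for j, e in enumerate(exons) if j != i])
        )
    gene = GeneAnnotation(GENE_ID, GENE_NAME, span, transcripts)
    rng = np.random.default_rng(seed)
    genome_seq = _random_seq(span.end + FLANK, rng)
    return gene, genome_seq


def default_truth(
    seed: int = 0,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    p_tss_missing: float = 0.3,
    p_polya_missing: float = 0.3,
) -> FixtureTruth:
    """The standard study conditions used throughout the test suite.

    A 7-exon gene (one 10 kb intron for the compression stage); three
    isoforms — full-length, cassette-exon-2 skipped, exon-4 skipped — at
    cell-type-specific proportions so the cassette exon's true Psi
    differs between cell types; four injected mismatch sites spanning the
    three event kinds and frequencies on both sides of the default 5-95%
    window; 30% of reads lack a TSS/PolyA assignment.
    """
    gene, genome_seq = make_toy_gene(seed=seed)
    n = len(DEFAULT_EXON_LENGTHS)
    full = tuple(range(n))
    skip2 = tuple(i for i in range(n) if i != 2)
    skip4 = tuple(i for i in range(n) if i != 4)

    props_by_ct = {}
    patterns = [(0.6, 0.3, 0.1), (0.2, 0.7, 0.1), (0.45, 0.45, 0.1)]
    for i, ct in enumerate(cell_types):
        props_by_ct[ct] = patterns[i % len(patterns)]
    isoform_table = [
        (full, {ct: props_by_ct[ct][0] for ct in cell_types}),
        (skip2, {ct: props_by_ct[ct][1] for ct in cell_types}),
        (skip4, {ct: props_by_ct[ct][2] for ct in cell_types}),
    ]
    inclusion = {
        ct: {
            i: sum(p[ct] for idxs, p in isoform_table if i in idxs)
            for i in range(n)
        }
        for ct in cell_types
    }
    exons = gene.transcripts[0][1]
    injected = [
        InjectedSite(exons[0].start + 30, SNV, 1, 0.01),
        InjectedSite(exons[1].start + 40, SNV, 1, 0.10),
        InjectedSite(exons[5].start + 50, INSERTION, 2, 0.30),
        InjectedSite(exons[6].start + 60, DELETION, 3, 0.96),
    ]
    return FixtureTruth(
        gene=gene,
        genome_seq=genome_seq,
        isoform_table=isoform_table,
        exon_inclusion_rates=inclusion,
        injected_sites=injected,
        seed=seed,
        p_tss_missing=p_tss_missing,
        p_polya_missing=p_polya_missing,
    )


def _read_covers(exons: Sequence[GenomicInterval], site: InjectedSite) -> bool:
    if site.kind == INSERTION:
        need = GenomicInterval(CHROM, site.pos - 1, site.pos + 1)
    elif site.kind == DELETION:
        need = GenomicInterval(CHROM, site.pos, site.pos + site.length)
    else:
        need = GenomicInterval(CHROM, site.pos, site.pos + 1)
    return any(e.contains(need) for e in exons)


def simulate_reads(
    truth: FixtureTruth,
    n_per_celltype: Optional[dict[str, int]] = None,
    seed: int = 1,
    outdir: Optional[str | Path] = None,
) -> SimulatedDataset:
    """Draw reads from the isoform table and inject mismatch events.

    Per cell type, isoform counts are multinomial in the table's
    proportions; per covering read, each injected site fires as an
    independent Bernoulli at its frequency. With ``outdir`` set, the
    dataset is written in every dialect: reads.gff, assignments.tsv,
    allinfo.tsv, reads.sam, genome.fa and truth.json.
    """
    if n_per_celltype is None:
        n_per_celltype = {ct: 100 for ct in truth.cell_types}
    rng = np.random.default_rng(seed)
    exon_set = truth.exons
    reads: list[ReadIsoform] = []
    read_iso: dict[str, int] = {}
    read_events: dict[str, list[InjectedSite]] = {}
    site_support: dict[int, int] = {s.pos: 0 for s in truth.injected_sites}

    for ct in truth.cell_types:
        n = n_per_celltype.get(ct, 0)
        props = [p[ct] for _, p in truth.isoform_table]
        counts = rng.multinomial(n, props)
        idx = 0
        for iso_i, c in enumerate(counts):
            exon_idxs = truth.isoform_table[iso_i][0]
            exons = [exon_set[i] for i in exon_idxs]
            for _ in range(c):
                rid = f"{ct}_r{idx:04d}"
                idx += 1
                tss = None if rng.random() < truth.p_tss_missing else exons[0].start
                polya = None if rng.random() < truth.p_polya_missing else exons[-1].end
                read = ReadIsoform(
                    read_id=rid,
                    exons=exons,
                    gene_id=truth.gene.gene_id,
                    cell_type=ct,
                    barcode=f"BC{zlib.crc32(rid.encode()) % 10**6:06d}",
                    tss=tss,
                    polya=polya,
                )
                events = [
                    s
                    for s in truth.injected_sites
                    if _read_covers(exons, s) and rng.random() < s.frequency
                ]
                for s in events:
                    site_support[s.pos] += 1
                reads.append(read)
                read_iso[rid] = iso_i
                read_events[rid] = events

    ds = SimulatedDataset(truth, reads, read_iso, read_events, site_support)
    if outdir is not None:
        _write_all(ds, Path(outdir))
    return ds


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def _event_alleles(site: InjectedSite, genome: str) -> tuple[str, str]:
    """Deterministic alleles: alt bases are the cyclic successor of reference."""
    if site.kind == SNV:
        ref = genome[site.pos]
        return ref, _NEXT_BASE[ref]
    if site.kind == DELETION:
        return genome[site.pos : site.pos + site.length], ""
    anchor = genome[site.pos - 1]
    return "", _NEXT_BASE[anchor] * site.length


def _read_to_sam(
    read: ReadIsoform, events: list[InjectedSite], truth: FixtureTruth,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    """Emit an alignment whose CIGAR/SEQ encode the splices and events exactly."""
    genome = truth.genome_seq
    events = sorted(events, key=lambda s: s.pos)
    cigar: list[tuple[int, int]] = []
    seq_parts: list[str] = []

    def emit(op: int, length: int) -> None:
        if length == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    prev_end = None
    for exon in read.exons:
        if prev_end is not None:
            emit(3, exon.start - prev_end)  # N: intron
        pos = exon.start
        for site in [s for s in events if exon.start <= s.pos < exon.end]:
            if site.kind == SNV:
                seq_parts.append(genome[pos : site.pos])
                ref, alt = _event_alleles(site, genome)
                seq_parts.append(alt)
                emit(0, site.pos - pos + 1)
                pos = site.pos + 1
            elif site.kind == INSERTION:
                seq_parts.append(genome[pos : site.pos])
                emit(0, site.pos - pos)
                _, alt = _event_alleles(site, genome)
                seq_parts.append(alt)
                emit(1, len(alt))
                pos = site.pos
            else:  # deletion
                seq_parts.append(genome[pos : site.pos])
                emit(0, site.pos - pos)
                emit(2, site.length)
                pos = site.pos + site.length
        seq_parts.append(genome[pos : exon.end])
        emit(0, exon.end - pos)
        prev_end = exon.end

    a = pysam.AlignedSegment(header)
    a.query_name = read.read_id
    a.query_sequence = "".join(seq_parts)
    a.flag = 0
    a.reference_id = 0
    a.reference_start = read.exons[0].start
    a.mapping_quality = 60
    a.cigartuples = cigar
    return a


def _write_all(ds: SimulatedDataset, outdir: Path) -> None:
    from .io import write_allinfo

    outdir.mkdir(parents=True, exist_ok=True)
    truth = ds.truth
    paths = {
        "gff": outdir / "reads.gff",
        "assignments": outdir / "assignments.tsv",
        "allinfo": outdir / "allinfo.tsv",
        "sam": outdir / "reads.sam",
        "fasta": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "truth": outdir / "truth.json",
    }

    with open(paths["gff"], "w") as fh:
        for r in ds.reads:
            for e in r.exons:
                attrs = f'gene_id "{r.gene_id}"; transcript_id "{r.read_id}";'
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )

    with open(paths["assignments"], "w") as fh:
        fh.write("read_id\tgene_id\tcell_type\tbarcode\n")
        for r in ds.reads:
            fh.write(f"{r.read_id}\t{r.gene_id}\t{r.cell_type}\t{r.barcode}\n")

    write_allinfo(ds.reads, str(paths["allinfo"]))

    with open(paths["annotation"], "w") as fh:
        g = truth.gene
        base = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
        fh.write(
            f"{CHROM}\tsim\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t+\t.\t{base}\n"
        )
        for tx_id, exons in g.transcripts:
            fh.write(
                f"{CHROM}\tsim\ttranscript\t{exons[0].start + 1}\t{exons[-1].end}"
                f"\t.\t+\t.\t{base} transcript_id \"{tx_id}\";\n"
            )
            for e in exons:
                fh.write(
                    f"{CHROM}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t+\t.\t"
                    f'{base} transcript_id "{tx_id}";\n'
                )

    with open(paths["fasta"], "w") as fh:
        fh.write(f">{CHROM}\n")
        seq = truth.genome_seq
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": CHROM, "LN": len(truth.genome_seq)}],
        }
    )
    recs = [
        _read_to_sam(r, ds.read_events[r.read_id], truth, header) for r in ds.reads
    ]
    recs.sort(key=lambda a: (a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as sam:
        for rec in recs:
            sam.write(rec)

    genome = truth.genome_seq
    truth_json = {
        "seed": truth.seed,
        "gene_id": truth.gene.gene_id,
        "chrom": CHROM,
        "span": [truth.gene.span.start, truth.gene.span.end],
        "exons": [[e.start, e.end] for e in truth.exons],
        "isoform_table": [
            {"exon_indices": list(idxs), "proportions": props}
            for idxs, props in truth.isoform_table
        ],
        "exon_inclusion_rates": {
            ct: {str(i): p for i, p in rates.items()}
            for ct, rates in truth.exon_inclusion_rates.items()
        },
        "injected_sites": [
            {
                "pos": s.pos,
                "kind": s.kind,
                "ref": _event_alleles(s, genome)[0],
                "alt": _event_alleles(s, genome)[1],
                "frequency": s.frequency,
                "realized_support": ds.site_support[s.pos],
            }
            for s in truth.injected_sites
        ],
        "n_reads": {
            ct: sum(1 for r in ds.reads if r.cell_type == ct)
            for ct in truth.cell_types
        },
        "reads_missing_tss": sum(1 for r in ds.reads if r.tss is None),
        "reads_missing_polya": sum(1 for r in ds.reads if r.polya is None),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1)

    ds.paths = paths
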