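"""Readers and writers for every external format the tool touches.

Internal convention is 0-based half-open everywhere; GFF/GTF input
(1-based inclusive) and the AllInfo dialect (1-based inclusive pairs) are
converted exactly at this boundary, and BED12 output is native 0-based
half-open. All text inputs may be gzip-compressed (detected by ``.gz``).

Supported inputs:

* per-read exon structures as GFF/GTF (exon features grouped by a
  read/transcript identifier attribute), paired with a tab-delimited
  read -> (gene, cell type[, barcode]) assignment table;
* the combined per-read "AllInfo" dialect: one line per read carrying
  gene, cell type, TSS, PolyA and the intron/exon structure. The column
  schema used here (see :data:`ALLINFO_COLUMNS`) is this package's
  documented layout for that dialect;
* GENCODE-style GTF/GFF3 gene annotation (via gffutils);
* BED12 track export for the UCSC genome browser.
"""

from __future__ import annotations

import gzip
import logging
from typing import IO, Iterator, Optional

import gffutils

from .model import (
    FormatError,
    GeneAnnotation,
    GenomicInterval,
    LookupError_,
    ReadIsoform,
)

logger = logging.getLogger(__name__)

#: Column layout of the AllInfo per-read dialect, tab-delimited, one read
#: per line. ``tss``/``polya`` are 0-based positions or the sentinel ``.``
#: (``NA`` also accepted); ``intron_chain``/``exon_chain`` are
#: semicolon-separated ``start-end`` pairs, 1-based inclusive; an empty
#: intron chain (mono-exonic read) is the sentinel.
ALLINFO_COLUMNS = (
    "read_id",
    "gene_id",
    "cell_type",
    "barcode",
    "chrom",
    "strand",
    "tss",
    "polya",
    "intron_chain",
    "exon_chain",
)

_SENTINELS = {".", "NA", "NaN", ""}


def _open(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_attributes(field: str) -> dict[str, str]:
    """Parse GFF3 (``k=v;``) or GTF (``k "v";``) attribute strings."""
    attrs: dict[str, str] = {}
    for part in field.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part and '"' not in part:
            k, _, v = part.partition("=")
            attrs[k.strip()] = v.strip().strip('"')
        else:
            k, _, v = part.partition(" ")
            attrs[k.strip()] = v.strip().strip('"')
    return attrs


def _exons_to_read(
    read_id: str, raw_exons: list[GenomicInterval], **kw
) -> ReadIsoform:
    """Sort exon blocks and merge book-ended ones (0-length gaps).

    A 0-length gap is a representation artifact, not a splice; gaps of
    >=1 base are introns and are preserved.
    """
    raw_exons = sorted(raw_exons, key=lambda e: (e.start, e.end))
    merged: list[GenomicInterval] = []
    for e in raw_exons:
        if merged and e.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, e.end), prev.strand
            )
        else:
            merged.append(e)
    return ReadIsoform(read_id=read_id, exons=merged, **kw)


# ---------------------------------------------------------------------------
# per-read GFF + assignment table
# ---------------------------------------------------------------------------

_READ_ID_KEYS = ("read_id", "transcript_id", "ID", "Parent")


def parse_read_gff(
    path: str, gene_filter: Optional[str] = None
) -> list[ReadIsoform]:
    """Parse per-read exon structures from a GFF/GTF mapping file.

    Returns one partial ReadIsoform per distinct read id (exons only;
    gene/cell-type metadata comes from the assignment table). Output is
    sorted by read id, so it is independent of input line order.
    ``gene_filter`` keeps only reads whose ``gene_id`` attribute matches;
    a filter matching nothing yields an empty list, not an error.
    """
    exons_by_read: dict[str, list[GenomicInterval]] = {}
    genes_by_read: dict[str, str] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-delimited columns, "
                    f"got {len(fields)}"
                )
            if fields[2].lower() != "exon":
                continue
            chrom, start_s, end_s, strand = fields[0], fields[3], fields[4], fields[6]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            attrs = _parse_attributes(fields[8])
            read_id = next((attrs[k] for k in _READ_ID_KEYS if k in attrs), None)
            if read_id is None:
                raise FormatError(
                    f"{path}:{lineno}: exon feature lacks a read identifier "
                    f"attribute (one of {_READ_ID_KEYS})"
                )
            gene = attrs.get("gene_id", attrs.get("gene", ""))
            genes_by_read.setdefault(read_id, gene)
            # GFF 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            exons_by_read.setdefault(read_id, []).append(iv)

    reads = []
    for read_id in sorted(exons_by_read):
        if gene_filter is not None and genes_by_read.get(read_id) != gene_filter:
            continue
        reads.append(
            _exons_to_read(read_id, exons_by_read[read_id], gene_id=genes_by_read.get(read_id, ""))
        )
    return reads


def parse_assignment_table(path: str) -> dict[str, tuple[str, str, Optional[str]]]:
    """Read -> (gene_id, cell_type, barcode) assignment table.

    Tab-delimited, one row per read: read_id, gene_id, cell_type and an
    optional barcode column. A read assigned twice is a format error;
    reads absent from the table are simply absent from the map.
    """
    out: dict[str, tuple[str, str, Optional[str]]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("read_id", "readid", "read"):
                continue  # header row
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 columns "
                    "(read_id, gene_id, cell_type[, barcode]), got "
                    f"{len(fields)}"
                )
            read_id, gene_id, cell_type = fields[0], fields[1], fields[2]
            barcode = fields[3] if len(fields) > 3 and fields[3] not in _SENTINELS else None
            if read_id in out:
                raise FormatError(
                    f"{path}:{lineno}: read {read_id!r} assigned more than once"
                )
            out[read_id] = (gene_id, cell_type, barcode)
    return out


def assemble_reads(
    gff_reads: list[ReadIsoform],
    assignments: dict[str, tuple[str, str, Optional[str]]],
    gene_id: Optional[str] = None,
) -> list[ReadIsoform]:
    """Join per-read exon structures with the assignment table.

    Reads without an assignment are dropped (they were not mapped to a
    gene); ``gene_id`` restricts to one gene.
    """
    out = []
    for read in gff_reads:
        if read.read_id not in assignments:
            continue
        g, ct, bc = assignments[read.read_id]
        if gene_id is not None and g != gene_id:
            continue
        out.append(
            ReadIsoform(
                read_id=read.read_id,
                exons=read.exons,
                gene_id=g,
                cell_type=ct,
                barcode=bc,
                tss=read.tss,
                polya=read.polya,
            )
        )
    return out


# ---------------------------------------------------------------------------
# AllInfo dialect
# ---------------------------------------------------------------------------


def _parse_chain(field: str, what: str) -> list[tuple[int, int]]:
    """Parse a ``start-end;start-end`` 1-based inclusive pair list."""
    if field in _SENTINELS:
        return []
    pairs = []
    for token in field.split(";"):
        a, sep, b = token.partition("-")
        if not sep:
            raise ValueError(f"bad {what} token {token!r}")
        pairs.append((int(a) - 1, int(b)))  # -> 0-based half-open
    return pairs


def parse_allinfo(
    path: str,
    gene_filter: Optional[str] = None,
    strict: bool = True,
) -> list[ReadIsoform]:
    """Parse the combined per-read AllInfo dialect.

    Each record already carries gene, cell type, TSS, PolyA and the
    intron/exon structure (see :data:`ALLINFO_COLUMNS`); sentinel TSS and
    PolyA values become absent. Records whose intron chain disagrees with
    the gaps between their exons are rejected: in strict mode (default)
    all offending read ids are reported in one error, in lenient mode
    they are skipped with a logged count.
    """
    reads: list[ReadIsoform] = []
    bad: list[str] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(ALLINFO_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(ALLINFO_COLUMNS)} columns "
                    f"({', '.join(ALLINFO_COLUMNS)}), got {len(fields)}"
                )
            rec = dict(zip(ALLINFO_COLUMNS, fields))
            if gene_filter is not None and rec["gene_id"] != gene_filter:
                continue
            try:
                exon_pairs = _parse_chain(rec["exon_chain"], "exon")
                intron_pairs = _parse_chain(rec["intron_chain"], "intron")
                if not exon_pairs:
                    raise ValueError("record has no exons")
                gaps = [
                    (a_end, b_start)
                    for (_, a_end), (b_start, _) in zip(exon_pairs, exon_pairs[1:])
                ]
                if gaps != intron_pairs:
                    raise ValueError(
                        f"intron chain {intron_pairs} disagrees with exon gaps {gaps}"
                    )
                tss = None if rec["tss"] in _SENTINELS else int(rec["tss"])
                polya = None if rec["polya"] in _SENTINELS else int(rec["polya"])
                barcode = None if rec["barcode"] in _SENTINELS else rec["barcode"]
                chrom = rec["chrom"]
                strand = rec["strand"] if rec["strand"] in "+-" else "."
                reads.append(
                    ReadIsoform(
                        read_id=rec["read_id"],
                        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs],
                        gene_id=rec["gene_id"],
                        cell_type=rec["cell_type"],
                        barcode=barcode,
                        tss=tss,
                        polya=polya,
                    )
                )
            except (ValueError, FormatError) as exc:
                bad.append(f"{rec['read_id']} (line {lineno}): {exc}")
    if bad:
        if strict:
            raise FormatError(
                f"{path}: {len(bad)} inconsistent record(s):\n  " + "\n  ".join(bad)
            )
        logger.warning("%s: skipped %d inconsistent record(s)", path, len(bad))
    return reads


def write_allinfo(reads: list[ReadIsoform], path: str) -> None:
    """Write reads in the AllInfo dialect (inverse of :func:`parse_allinfo`)."""
    from .cluster import derive_intron_chain

    with open(path, "w") as fh:
        for r in reads:
            chain = derive_intron_chain(r)
            introns = ";".join(f"{i.start + 1}-{i.end}" for i in chain.introns) or "."
            exons = ";".join(f"{e.start + 1}-{e.end}" for e in r.exons)
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.gene_id,
                        r.cell_type,
                        r.barcode or ".",
                        r.chrom,
                        r.strand,
                        "." if r.tss is None else str(r.tss),
                        "." if r.polya is None else str(r.polya),
                        introns,
                        exons,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene annotation (GENCODE GTF / GFF3)
# ---------------------------------------------------------------------------


def parse_annotation(path: str, gene_id: str) -> GeneAnnotation:
    """Load one gene's transcript models from a GENCODE-style GTF/GFF3."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_exons: dict[str, list[GenomicInterval]] = {}
    gene_name = gene_id
    span: Optional[GenomicInterval] = None
    for feat in db.all_features():
        attrs = feat.attributes
        g = (attrs.get("gene_id") or attrs.get("gene") or [None])[0]
        if g != gene_id:
            continue
        strand = feat.strand if feat.strand in "+-" else "."
        if feat.featuretype == "gene":
            span = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            gene_name = (attrs.get("gene_name") or [gene_id])[0]
        elif feat.featuretype == "exon":
            tx = (attrs.get("transcript_id") or attrs.get("Parent") or [None])[0]
            if tx is None:
                raise FormatError(f"{path}: exon of gene {gene_id} lacks transcript_id")
            tx_exons.setdefault(tx, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            )
    if span is None and not tx_exons:
        raise LookupError_(f"gene {gene_id!r} not found in {path}")
    if span is None:
        allx = [e for exs in tx_exons.values() for e in exs]
        span = GenomicInterval(
            allx[0].chrom,
            min(e.start for e in allx),
            max(e.end for e in allx),
            allx[0].strand,
        )
    return GeneAnnotation(
        gene_id=gene_id,
        gene_name=gene_name,
        span=span,
        transcripts=[(tx, sorted(exs)) for tx, exs in sorted(tx_exons.items())],
    )


# ---------------------------------------------------------------------------
# UCSC browser track (BED12)
# ---------------------------------------------------------------------------


def write_ucsc_track(
    reads: list[ReadIsoform], path: str, track_name: str = "isostack_reads"
) -> None:
    """Write one BED12 line per read for upload to the UCSC genome browser.

    chromStart/chromEnd span the read; blockCount/blockSizes/blockStarts
    encode its exon blocks exactly. Writing then re-parsing reproduces
    each read's exon structure (0-based half-open throughout).
    """
    if not reads:
        raise ValueError("no reads to export; file not written")
    chroms = {r.chrom for r in reads}
    if len(chroms) != 1:
        raise ValueError(f"reads span multiple chromosomes: {sorted(chroms)}")
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" itemRgb="On"\n')
        for r in reads:
            span = r.span
            sizes = ",".join(str(len(e)) for e in r.exons) + ","
            starts = ",".join(str(e.start - span.start) for e in r.exons) + ","
            strand = r.strand if r.strand in "+-" else "."
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(span.start),
                        str(span.end),
                        r.read_id,
                        "0",
                        strand,
                        str(span.start),
                        str(span.end),
                        "0,0,0",
                        str(len(r.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str) -> list[ReadIsoform]:
    """Parse a BED12 track file back into reads (exon structure only)."""
    reads = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [
                GenomicInterval(
                    chrom,
                    chrom_start + off,
                    chrom_start + off + size,
                    strand if strand in "+-" else ".",
                )
                for off, size in zip(starts, sizes)
            ]
            reads.append(ReadIsoform(read_id=name, exons=exons))
    return reads
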