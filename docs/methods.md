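# Methods

## Coordinate model

All internal coordinates are 0-based half-open on a single chromosome.
GTF/GFF input (1-based inclusive) and the AllInfo dialect's coordinate
pairs (1-based inclusive) are converted exactly at the I/O boundary;
BED12 output is native 0-based half-open. Book-ended exon blocks (a
0-length gap) are merged on input: a 0-length gap is a representation
artifact, not a splice. Gaps of ≥1 base are introns.

## Input dialects

Two routes produce the same in-memory reads:

1. **GFF + assignment table** — exon features grouped by a
   read/transcript identifier attribute, joined with a tab-delimited
   `read_id, gene_id, cell_type[, barcode]` table. Reads absent from the
   table are dropped; a read assigned twice is an error.
2. **AllInfo** — one line per read already carrying gene, cell type,
   TSS, PolyA and the exon/intron structure. The column order of this
   dialect is not standardized anywhere we could adopt it from, so this
   package documents its own schema
   (`read_id, gene_id, cell_type, barcode, chrom, strand, tss, polya,
   intron_chain, exon_chain`, `.` sentinels, 1-based inclusive `start-end`
   pairs); files from other tools may need a column reorder. Records
   whose intron chain disagrees with their exon gaps are rejected
   (strict mode, default) or skipped with a logged count (lenient).

TSS and PolyA values are consumed as given — they are assigned and
binned upstream — and no positional fuzz is applied to them or to splice
sites anywhere in the package.

## Coordinate compression

The plot axis is built from the union of *all* exonic evidence:
annotation exons plus every read's exon blocks. Union blocks become
real-scale segments; the maximal exon-free gaps between them (including
the flanks before the first and after the last block) become compressed
segments of plot width `min(gap_length, compressed_width)` with
`compressed_width = 100` bases by default. Consequences, by design:

- compression never enlarges: gaps at or below 100 bases stay at real
  scale;
- an intron retained in even one read is exonic evidence and keeps that
  region at real scale — short retained introns are therefore drawn to
  scale;
- only the single 100-base rule is implemented; no separate threshold
  for very large introns exists, and `compressed_width` is exposed as an
  option.

Positions map through an exact shift inside real segments and linear
interpolation inside compressed ones; plot positions are real-valued and
rounded only at render time. The transform is non-decreasing everywhere
and strictly increasing between positions in real segments.

## Clustering

The clustering key is the intron chain — the ordered list of gaps
between exon blocks — compared by exact coordinate equality: two reads
differing by one base at one splice site form distinct clusters.
Mono-exonic reads share the empty chain (one cluster per cell type under
chain mode); they carry no splice information to separate them. Modes
`tss+chain`, `chain+polya` and `tss+chain+polya` add the read's TSS
and/or PolyA value to the key and exclude (with a reported count) reads
lacking it.

Display order within a cell type is not something the read data dictate,
so it is a documented deterministic comparator: descending cluster size,
then more introns first, then lexicographic on intron coordinates
(`by_size`, default), or ascending leftmost read start (`by_position`).
Reads within a cluster order by (span start, span end, read id). Cell
types display in the user-given order, else lexicographically.

## Alternative exons

The candidate unit is the exact `(start, end)` exon variant pooled from
annotation and reads; overlapping variants with different boundaries are
scored independently. For one candidate exon:

- **overlapping** — reads whose genomic footprint (first exon start to
  last exon end) intersects the exon by ≥1 base, so a read that splices
  the exon out counts in the denominator;
- **included** — overlapping reads with one exon block fully containing
  the candidate interval, so a retained-intron block containing the exon
  region counts as inclusion (exact splice-site matching would be a
  stricter dialect; the containment reading is the simplest one
  consistent with Ψ as an inclusion fraction).

Ψ = included/overlapping, pooled across all cell types; zero overlap
leaves Ψ undefined and the exon unflagged. The alternative flag is the
closed window `lower ≤ 100·Ψ ≤ upper`, default 5–95, with 20–80 as the
preset for higher-error chemistries. Both endpoints are inclusive.

## Mismatch finding

CIGAR walking: `M/=/X` columns are compared base-by-base against the
reference; `I`/`D` operations become single events keyed by position and
allele string (one biological event, one record); `N` is a splice, never
a deletion. An insertion's reference position is the base following the
insertion point. Distances for end exclusion are measured along the
reference within the read's own alignment, 1-based from each alignment
end; an insertion anchors on its left flanking base, a deletion measures
its first base from the start and its last from the end. Observations
with either distance ≤ `margin` (default 20) are dropped; the filter is
idempotent.

Aggregation groups observations by (position, kind, alleles); support
counts distinct read ids. The frequency denominator is per-site
alignment coverage (SNV: the position; deletion: the whole deleted
interval; insertion: both flanking bases), pooled across all cell types,
mirroring the Ψ pooling; a per-gene denominator would be the natural
config alternative but per-site coverage is what the frequency of "
overlapping reads" means once reads have different footprints. The
closed window (default 5–95%) sets the pass flag; homozygous-difference
sites near 100% are suppressed by default and recoverable with
`upper = 100`.

## Rendering

One row per read, rows contiguous per cell type, annotation transcripts
at the bottom restricted to those overlapping the read-covered span
(unclipped). Exon blocks that exactly match a flagged alternative exon
are drawn whole in the alternative color (orange); larger blocks
(retained introns) keep the cell-type color with only the matching
sub-interval recolored (togglable). Mismatch dots are drawn on every
read row carrying the observation when per-read observations are
available, else once on a summary row; SNV blue, insertion green,
deletion red, all user-overridable. Intron connectors are thin
horizontal lines. Figure height grows linearly with row count; width is
set by the compressed axis length. Static output goes through
matplotlib; the interactive output is a self-contained HTML page
embedding an SVG whose glyphs carry `<title>` tooltips (read id, cell
type, cluster size; site kind and frequency) — no JavaScript or external
libraries, so the file works offline in any browser.

## Synthetic data generator

The generator exists so every stage has a ground truth. Defaults, chosen
once as a realistic desk-scale gene: 7 exons (90–250 bp) separated by
introns of 0.8–10 kb (one 10 kb intron exercises compression); three
isoforms — full-length, cassette-exon skip, a second internal-exon
skip — at per-cell-type proportions (0.6/0.3/0.1, 0.2/0.7/0.1,
0.45/0.45/0.1 across three cell types), so the cassette exon's true Ψ
differs by cell type (0.7/0.3/0.55, pooled ≈0.52); four injected
mismatch sites covering all three event kinds at frequencies 1%, 10%,
30% and 96% — two inside and two outside the default window; 30% of
reads lack a TSS (and independently a PolyA) assignment; 100 reads per
cell type. Isoform counts are multinomial, events are per-read
Bernoulli, and all sampling flows from one `numpy.random.default_rng`
seed, so output is reproducible across platforms. Alt alleles are the
cyclic successor (A→C→G→T→A) of the reference base, guaranteeing a
difference deterministically.

Reads are full-length with exact splice sites; SAM records carry exact
CIGARs (`N` for introns, `I`/`D` for injected indels, substitutions as
`M` with a differing base). The generator does **not** emulate read
truncation, splice-site wobble, correlated base errors or
chemistry-specific error profiles — tests passing on it show the
bookkeeping (counts, windows, transforms, round trips) is exact, not
that the method is robust to those artifacts on real data.

## Numerical choices and degenerate inputs

- Windows are closed on both ends; an inverted window is a parameter
  error, and (0, 100) degenerates to "flag/surface everything covered".
- Zero overlapping reads ⇒ Ψ undefined, never flagged; zero coverage ⇒
  a site cannot pass.
- An empty exonic set leaves the whole span at real scale with a
  warning, not an error; an empty cluster list is a hard error
  ("nothing to plot").
- All orderings are total and deterministic; reruns of the same config
  on the same inputs produce identical tables and glyph counts.

## Problem sizes in the test suite

The suites run on the generator defaults (300 reads) for pipeline-level
checks, ≤50-read fixtures for exact brute-force oracle comparisons, and
2,000 reads for statistical recovery checks (empirical Ψ and injected
mismatch frequencies within 3 binomial standard errors of truth). These
sizes make every statistical assertion sharp at desk scale.

## Known limitations

- Single gene, single chromosome per plot; no multi-gene maps.
- No statistical test for differential inclusion across cell types and
  no formal mutually-exclusive-exon call; such patterns are visible in
  the stacks but not computed as statistics.
- No base-quality-aware error model, genotyping or phasing in the
  mismatch finder.
- TSS/PolyA are trusted as given; no peak calling or re-binning.
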