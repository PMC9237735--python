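"""Intron-chain derivation and per-cell-type read clustering.

Reads are grouped by their chain of introns — the ordered list of gaps
between a read's exon blocks — optionally combined with TSS and/or PolyA
site. Chain equality is exact coordinate equality: two reads differing by
a single base at one splice site form distinct clusters (no fuzz; splice
sites are taken as assigned upstream).

When the clustering mode includes TSS (resp. PolyA), reads lacking that
key are excluded from plotting and their count reported, mirroring the
convention that only reads with an assigned TSS/PolyA site are shown
under those modes.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .model import GenomicInterval, ReadIsoform

ClusterMode = Literal["chain", "tss+chain", "chain+polya", "tss+chain+polya"]

CLUSTER_MODES: tuple[str, ...] = ("chain", "tss+chain", "chain+polya", "tss+chain+polya")


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron coordinates of one read; empty for mono-exonic reads."""

    introns: tuple[GenomicInterval, ...]

    def __len__(self) -> int:
        return len(self.introns)

    @property
    def key(self) -> tuple[tuple[int, int], ...]:
        """Hashable canonical form: ((start, end), ...)."""
        return tuple((i.start, i.end) for i in self.introns)

    def __str__(self) -> str:
        return ";".join(f"{i.start}-{i.end}" for i in self.introns) or "."


@dataclass(frozen=True)
class ClusterKey:
    chain: IntronChain
    mode: str = "chain"
    tss_bin: Optional[int] = None
    polya_bin: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in CLUSTER_MODES:
            raise ValueError(f"unknown clustering mode {self.mode!r}")
        if ("tss" in self.mode) != (self.tss_bin is not None):
            raise ValueError("tss_bin must be present iff mode includes tss")
        if ("polya" in self.mode) != (self.polya_bin is not None):
            raise ValueError("polya_bin must be present iff mode includes polya")


@dataclass
class IsoformCluster:
    """Reads of one cell type sharing a ClusterKey."""

    key: ClusterKey
    cell_type: str
    reads: list[ReadIsoform] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class ClusterResult:
    """Clusters grouped by cell type plus per-cell-type exclusion counts."""

    clusters: list[IsoformCluster]
    excluded: dict[str, int]
    mode: str

    @property
    def n_retained(self) -> int:
        return sum(c.size for c in self.clusters)

    def by_cell_type(self) -> dict[str, list[IsoformCluster]]:
        out: dict[str, list[IsoformCluster]] = defaultdict(list)
        for c in self.clusters:
            out[c.cell_type].append(c)
        return dict(out)


def derive_intron_chain(read: ReadIsoform) -> IntronChain:
    """Introns are the gaps between consecutive exon blocks."""
    introns = tuple(
        GenomicInterval(read.chrom, a.end, b.start, read.strand)
        for a, b in zip(read.exons, read.exons[1:])
    )
    return IntronChain(introns)


def _key_for(read: ReadIsoform, mode: str) -> Optional[ClusterKey]:
    """ClusterKey for the read under ``mode``; None if a required key is absent."""
    need_tss = "tss" in mode
    need_polya = "polya" in mode
    if need_tss and read.tss is None:
        return None
    if need_polya and read.polya is None:
        return None
    return ClusterKey(
        chain=derive_intron_chain(read),
        mode=mode,
        tss_bin=read.tss if need_tss else None,
        polya_bin=read.polya if need_polya else None,
    )


def cluster_reads(reads: Iterable[ReadIsoform], mode: str = "chain") -> ClusterResult:
    """Partition reads of one gene into per-cell-type isoform clusters.

    Every retained read lands in exactly one cluster; cluster sizes sum to
    the retained count. Under mode="chain" all reads are retained.
    """
    if mode not in CLUSTER_MODES:
        raise ValueError(f"unknown clustering mode {mode!r}; choose from {CLUSTER_MODES}")
    groups: dict[tuple[str, ClusterKey], IsoformCluster] = {}
    excluded: dict[str, int] = defaultdict(int)
    order: list[tuple[str, ClusterKey]] = []
    for read in reads:
        key = _key_for(read, mode)
        if key is None:
            excluded[read.cell_type] += 1
            continue
        gk = (read.cell_type, key)
        if gk not in groups:
            groups[gk] = IsoformCluster(key=key, cell_type=read.cell_type)
            order.append(gk)
        groups[gk].reads.append(read)
    clusters = [groups[g] for g in order]
    retained_cts = {c.cell_type for c in clusters}
    for ct, n in excluded.items():
        if ct not in retained_cts:
            warnings.warn(
                f"cell type {ct!r}: all {n} reads lack the {mode} key; omitted",
                stacklevel=2,
            )
    return ClusterResult(clusters=clusters, excluded=dict(excluded), mode=mode)


def _cluster_sort_key(cluster: IsoformCluster):
    # descending size, then more introns first, then lexicographic on coords
    return (-cluster.size, -len(cluster.key.chain), cluster.key.chain.key,
            cluster.key.tss_bin or 0, cluster.key.polya_bin or 0)


def order_clusters(
    clusters: list[IsoformCluster], by: str = "by_size"
) -> list[IsoformCluster]:
    """Deterministic display order for one cell type's clusters.

    ``by_size``: descending size, ties broken by intron count (more
    first) then lexicographically on intron coordinates.
    ``by_position``: ascending leftmost read start, same tie-breaks.
    """
    if by == "by_size":
        return sorted(clusters, key=_cluster_sort_key)
    if by == "by_position":
        return sorted(
            clusters,
            key=lambda c: (min(r.span.start for r in c.reads), _cluster_sort_key(c)),
        )
    raise ValueError(f"unknown cluster ordering {by!r}")


def order_reads_within_cluster(cluster: IsoformCluster) -> list[ReadIsoform]:
    """Canonical read order: (alignment start, alignment end, read_id)."""
    return sorted(cluster.reads, key=lambda r: (r.span.start, r.span.end, r.read_id))
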