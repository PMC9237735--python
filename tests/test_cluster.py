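"""Intron-chain derivation, clustering partitions and display ordering."""

import random
from collections import defaultdict

import pytest

from isostack import cluster_reads, derive_intron_chain, order_clusters
from isostack.cluster import order_reads_within_cluster

from conftest import make_read


class TestDeriveIntronChain:
    def test_introns_are_the_gaps_between_exons(self):
        r = make_read("r", [(0, 100), (200, 300)])
        chain = derive_intron_chain(r)
        assert chain.key == ((100, 200),)

    def test_mono_exonic_read_has_empty_chain(self):
        assert len(derive_intron_chain(make_read("r", [(0, 100)]))) == 0

    def test_chain_length_is_exon_count_minus_one(self, dataset):
        for read in dataset.reads:
            assert len(derive_intron_chain(read)) == len(read.exons) - 1

    def test_fixture_chains_match_generator_truth(self, truth, dataset):
        """The multiset of chains equals the isoform table's chains."""
        expected_chains = set()
        exons = truth.exons
        for idxs, _ in truth.isoform_table:
            chosen = [exons[i] for i in idxs]
            expected_chains.add(
                tuple((a.end, b.start) for a, b in zip(chosen, chosen[1:]))
            )
        observed = {derive_intron_chain(r).key for r in dataset.reads}
        assert observed == expected_chains


def _random_reads(rng, n=60):
    layouts = [
        [(0, 100), (200, 300), (400, 500)],
        [(0, 100), (400, 500)],
        [(0, 100), (210, 300), (400, 500)],  # 1-base splice difference
        [(50, 500)],
    ]
    reads = []
    for i in range(n):
        layout = rng.choice(layouts)
        reads.append(
            make_read(
                f"r{i:03d}",
                layout,
                cell_type=rng.choice(["A", "B"]),
                tss=layout[0][0] if rng.random() < 0.5 else None,
                polya=layout[-1][1] if rng.random() < 0.5 else None,
            )
        )
    return reads


class TestClusterReads:
    def test_partition_sizes_sum_to_input(self):
        reads = [
            make_read(f"r{i}", [(0, 100), (200 + 10 * (i % 3), 300)]) for i in range(10)
        ]
        result = cluster_reads(reads, mode="chain")
        assert len(result.clusters) == 3
        assert result.n_retained == 10

    def test_chain_mode_retains_every_read(self, dataset):
        result = cluster_reads(dataset.reads, mode="chain")
        assert result.n_retained == len(dataset.reads)
        assert result.excluded == {}

    def test_tss_mode_excludes_exactly_reads_lacking_tss(self, dataset):
        missing = sum(1 for r in dataset.reads if r.tss is None)
        result = cluster_reads(dataset.reads, mode="tss+chain")
        assert result.n_retained == len(dataset.reads) - missing
        assert sum(result.excluded.values()) == missing

    @pytest.mark.parametrize("mode", ["chain", "tss+chain", "chain+polya", "tss+chain+polya"])
    def test_every_retained_read_in_exactly_one_cluster(self, mode):
        reads = _random_reads(random.Random(5))
        result = cluster_reads(reads, mode=mode)
        ids = [r.read_id for c in result.clusters for r in c.reads]
        assert len(ids) == len(set(ids)) == result.n_retained

    def test_partition_matches_brute_force_grouping(self):
        """mode=chain equals grouping by exact intron-chain equality."""
        reads = _random_reads(random.Random(11))
        expected = defaultdict(set)
        for r in reads:
            expected[(r.cell_type, derive_intron_chain(r).key)].add(r.read_id)
        result = cluster_reads(reads, mode="chain")
        observed = {
            (c.cell_type, c.key.chain.key): {r.read_id for r in c.reads}
            for c in result.clusters
        }
        assert observed == dict(expected)

    def test_one_base_splice_difference_separates_clusters(self):
        r1 = make_read("r1", [(0, 100), (200, 300)])
        r2 = make_read("r2", [(0, 100), (201, 300)])
        assert len(cluster_reads([r1, r2]).clusters) == 2

    def test_all_excluded_cell_type_is_omitted_with_warning(self):
        reads = [make_read(f"r{i}", [(0, 100)], cell_type="A") for i in range(3)]
        with pytest.warns(UserWarning, match="A"):
            result = cluster_reads(reads, mode="tss+chain")
        assert result.clusters == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cluster_reads([make_read("r", [(0, 10)])], mode="polya")


class TestOrdering:
    def _clusters(self, sizes_and_layouts, rng):
        reads = []
        for i, (size, layout) in enumerate(sizes_and_layouts):
            for j in range(size):
                reads.append(make_read(f"c{i}_r{j}", layout))
        rng.shuffle(reads)
        return cluster_reads(reads).clusters

    def test_descending_size_then_chain_tiebreak(self):
        clusters = self._clusters(
            [(5, [(0, 10), (20, 30)]), (3, [(0, 10), (25, 30)]), (3, [(0, 30)])],
            random.Random(0),
        )
        ordered = order_clusters(clusters)
        assert [c.size for c in ordered] == [5, 3, 3]
        # among the ties, the spliced (1-intron) cluster precedes the mono-exonic
        assert len(ordered[1].key.chain) > len(ordered[2].key.chain)

    def test_order_is_invariant_to_input_permutation(self):
        spec = [(4, [(0, 10), (20, 30)]), (4, [(0, 10), (22, 30)]), (2, [(0, 30)])]
        a = order_clusters(self._clusters(spec, random.Random(1)))
        b = order_clusters(self._clusters(spec, random.Random(99)))
        assert [(c.size, c.key.chain.key) for c in a] == [
            (c.size, c.key.chain.key) for c in b
        ]

    def test_sorted_per_comparator_against_independent_sort(self, dataset):
        clusters = cluster_reads(dataset.reads).clusters
        ordered = order_clusters(clusters)
        assert {id(c) for c in ordered} == {id(c) for c in clusters}
        keys = [(-c.size, -len(c.key.chain), c.key.chain.key) for c in ordered]
        assert keys == sorted(keys)

    def test_reads_within_cluster_sorted_by_start_end_id(self):
        reads = [
            make_read("r2", [(0, 100), (200, 300)]),
            make_read("r1", [(0, 100), (200, 300)]),
        ]
        cluster = cluster_reads(reads).clusters[0]
        assert [r.read_id for r in order_reads_within_cluster(cluster)] == ["r1", "r2"]

    def test_within_cluster_order_stable_under_shuffle(self):
        rng = random.Random(3)
        reads = [make_read(f"r{i:02d}", [(0, 100), (200, 300)]) for i in range(30)]
        c1 = cluster_reads(reads).clusters[0]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        c2 = cluster_reads(shuffled).clusters[0]
        assert [r.read_id for r in order_reads_within_cluster(c1)] == [
            r.read_id for r in order_reads_within_cluster(c2)
        ]
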