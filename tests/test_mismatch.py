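"""Mismatch finding: CIGAR walking, end exclusion, site aggregation."""

import random

import pysam
import pytest

from isostack import (
    GenomicInterval,
    aggregate_sites,
    apply_end_exclusion,
    collect_observations,
    default_truth,
    find_mismatches,
    simulate_reads,
)
from isostack.mismatch import (
    DELETION,
    INSERTION,
    SNV,
    AlignmentSpan,
    MismatchObservation,
    refilter_sites,
)
from isostack.model import ParameterError

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 100000}]}
)

REF = "".join(random.Random(123).choice("ACGT") for _ in range(3000))
REGION = GenomicInterval("chrT", 0, 3000)


def make_aln(read_id, ref_start, cigar, seq):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = read_id
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = 0
    a.reference_start = ref_start
    a.mapping_quality = 60
    a.cigarstring = cigar
    return a


def mutate(seq, offset, base):
    return seq[:offset] + base + seq[offset + 1 :]


def other(base):
    return "A" if base != "A" else "C"


class TestCollectObservations:
    def test_read_identical_to_reference_yields_nothing(self):
        aln = make_aln("r0", 100, "500M", REF[100:600])
        obs, spans = collect_observations([aln], REF, REGION)
        assert obs == []
        assert spans == [AlignmentSpan("r0", "chrT", 100, 600)]

    def test_known_substitution_insertion_deletion(self):
        """One SNV at ref 150, a 2-base insertion before ref 300, a 3-base
        deletion of ref [400, 403): three observations, exact coordinates."""
        seq = (
            mutate(REF[100:300], 50, other(REF[150]))
            + "GG"
            + REF[300:400]
            + REF[403:600]
        )
        aln = make_aln("r1", 100, "200M2I100M3D197M", seq)
        obs, _ = collect_observations([aln], REF, REGION)
        assert len(obs) == 3
        snv, ins, dele = sorted(obs, key=lambda o: o.ref_pos)
        assert (snv.kind, snv.ref_pos, snv.ref_allele, snv.alt_allele) == (
            SNV, 150, REF[150], other(REF[150]),
        )
        assert (snv.dist_from_start, snv.dist_from_end) == (51, 450)
        assert (ins.kind, ins.ref_pos, ins.alt_allele) == (INSERTION, 300, "GG")
        assert (ins.dist_from_start, ins.dist_from_end) == (200, 301)
        assert (dele.kind, dele.ref_pos, dele.ref_allele) == (DELETION, 400, REF[400:403])
        assert (dele.dist_from_start, dele.dist_from_end) == (301, 198)

    def test_intron_gap_is_not_a_deletion(self):
        seq = REF[100:200] + REF[1200:1300]
        aln = make_aln("r2", 100, "100M1000N100M", seq)
        obs, spans = collect_observations([aln], REF, REGION)
        assert obs == []
        assert spans[0].ref_end == 1300

    def test_multibase_indels_are_single_events(self):
        seq = REF[0:50] + "TTTT" + REF[50:100]
        aln = make_aln("r3", 0, "50M4I50M", seq)
        obs, _ = collect_observations([aln], REF, REGION)
        assert len(obs) == 1 and obs[0].alt_allele == "TTTT"

    def test_records_without_cigar_are_skipped(self):
        a = pysam.AlignedSegment(HEADER)
        a.query_name = "bad"
        a.flag = 4
        obs, spans = collect_observations([a], REF, REGION)
        assert obs == [] and spans == []

    def test_pileup_matches_column_by_column_comparison(self):
        """Ten gapless reads with random substitutions: observations equal a
        brute-force per-column character comparison."""
        rng = random.Random(9)
        alns, expected = [], set()
        for i in range(10):
            start = rng.randrange(0, 2000)
            length = rng.randrange(200, 800)
            seq = REF[start : start + length]
            for _ in range(rng.randrange(0, 6)):
                off = rng.randrange(0, length)
                seq = mutate(seq, off, other(REF[start + off]))
            alns.append(make_aln(f"p{i}", start, f"{length}M", seq))
            for off, (a, b) in enumerate(zip(seq, REF[start : start + length])):
                if a != b:
                    expected.add((f"p{i}", start + off, b, a))
        obs, _ = collect_observations(alns, REF, REGION)
        assert {(o.read_id, o.ref_pos, o.ref_allele, o.alt_allele) for o in obs} == expected


class TestEndExclusion:
    def _obs(self, ds, de):
        return MismatchObservation("r", 0, SNV, "A", "C", ds, de)

    def test_boundary_at_margin_20(self):
        kept = apply_end_exclusion([self._obs(20, 500), self._obs(21, 500),
                                    self._obs(500, 20), self._obs(500, 21)], 20)
        assert [(o.dist_from_start, o.dist_from_end) for o in kept] == [(21, 500), (500, 21)]

    def test_margin_zero_is_identity(self):
        obs = [self._obs(1, 1), self._obs(5, 5)]
        assert apply_end_exclusion(obs, 0) == obs

    def test_idempotent(self):
        obs = [self._obs(d, 999) for d in range(1, 60)]
        once = apply_end_exclusion(obs)
        assert apply_end_exclusion(once) == once

    def test_matches_brute_force_filter(self):
        rng = random.Random(4)
        obs = [self._obs(rng.randrange(1, 60), rng.randrange(1, 60)) for _ in range(200)]
        kept = apply_end_exclusion(obs, 20)
        assert kept == [o for o in obs if o.dist_from_start > 20 and o.dist_from_end > 20]

    def test_negative_margin_rejected(self):
        with pytest.raises(ParameterError):
            apply_end_exclusion([], -1)


class TestAggregateSites:
    def _spans(self, n):
        return [AlignmentSpan(f"s{i}", "chrT", 0, 1000) for i in range(n)]

    def _snv_obs(self, n, pos=500):
        return [
            MismatchObservation(f"s{i}", pos, SNV, "A", "C", 100, 100) for i in range(n)
        ]

    @pytest.mark.parametrize("support,expected", [(4, False), (5, True), (95, True), (96, False)])
    def test_default_window_boundaries(self, support, expected):
        [site] = aggregate_sites(self._snv_obs(support), self._spans(100))
        assert site.passes is expected
        assert site.freq_pct == pytest.approx(support)

    def test_support_counts_distinct_reads_only(self):
        obs = self._snv_obs(5) + self._snv_obs(5)  # duplicated observations
        [site] = aggregate_sites(obs, self._spans(100))
        assert site.support == 5

    def test_deletion_denominator_requires_full_coverage(self):
        obs = [MismatchObservation("d0", 995, DELETION, "ACGTACGTAC", "", 900, 1)]
        spans = [AlignmentSpan("d0", "chrT", 0, 1005)] + [
            AlignmentSpan(f"x{i}", "chrT", 0, 1000) for i in range(3)  # end inside the deletion
        ]
        [site] = aggregate_sites(obs, spans)
        assert site.overlapping == 1

    def test_widening_the_window_never_removes_a_passing_site(self):
        sites = aggregate_sites(
            self._snv_obs(10) + self._snv_obs(50, pos=600), self._spans(100), 20, 80
        )
        narrow = {s.ref_pos for s in sites if s.passes}
        wide = {s.ref_pos for s in refilter_sites(sites, 5, 95) if s.passes}
        assert narrow <= wide

    def test_degenerate_window_surfaces_every_disagreement(self):
        sites = aggregate_sites(self._snv_obs(1), self._spans(100), 0, 100)
        assert all(s.passes for s in sites)


class TestOnSimulatedAlignments:
    def test_mismatch_free_fixture_yields_zero_observations(self, tmp_path):
        truth = default_truth(seed=3)
        truth.injected_sites.clear()
        ds = simulate_reads(truth, {ct: 30 for ct in truth.cell_types}, seed=5,
                            outdir=tmp_path)
        obs, spans = collect_observations(
            str(ds.paths["sam"]), str(ds.paths["fasta"]), truth.gene.span
        )
        assert obs == []
        assert len(spans) == len(ds.reads)

    def test_injected_site_frequencies_recovered_with_correct_flags(self, truth, dataset):
        """Injected frequencies around {1%, 10%, 30%, 96%}: the default 5-95%
        window keeps exactly the middle two, and support equals the
        generator's realized per-site counts."""
        sites, _ = find_mismatches(
            str(dataset.paths["sam"]), str(dataset.paths["fasta"]), truth.gene.span
        )
        assert len(sites) == len(truth.injected_sites)
        by_pos = {s.ref_pos: s for s in sites}
        for inj in truth.injected_sites:
            site = by_pos[inj.pos]
            assert site.kind == inj.kind
            assert site.support == dataset.site_support[inj.pos]
        flags = [by_pos[i.pos].passes for i in truth.injected_sites]
        assert flags == [False, True, True, False]
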