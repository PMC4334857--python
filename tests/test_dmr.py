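"""Chi-square DMR detection and ultra-DMR consensus."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from conftest import bh_oracle
from medipseq.dmr import (
    DMR,
    ContingencyTable2x2,
    bh_adjust,
    call_dmrs,
    chisq_test,
    merge_candidate_regions,
    ultra_dmrs,
)
from medipseq.intervals import AlignedReadSet, GenomicInterval
from medipseq.peaks import Peak


def peak(chrom, start, end):
    return Peak(GenomicInterval(chrom, start, end), read_count=10,
                lambda_local=1.0, p_value=1e-6)


def make_dmr(chrom, start, end, direction):
    return DMR(GenomicInterval(chrom, start, end),
               ContingencyTable2x2(10, 990, 40, 960), 17.0, 1e-5, 1e-4,
               4.0 if direction == "hyper" else 0.25, direction)


class TestMergeCandidates:
    def test_overlapping_peaks_union(self):
        cands = merge_candidate_regions([peak("chr1", 100, 300)],
                                        [peak("chr1", 250, 500)])
        assert [(c.start, c.end) for c in cands] == [(100, 500)]

    def test_disjoint_peaks_concatenate_sorted(self):
        cands = merge_candidate_regions(
            [peak("chr1", 1000, 1200)], [peak("chr1", 100, 300)])
        assert [(c.start, c.end) for c in cands] == [(100, 300), (1000, 1200)]

    def test_union_matches_bp_membership_oracle(self):
        rng = np.random.default_rng(0)
        peaks_a = [peak("chr1", int(s), int(s + rng.integers(50, 400)))
                   for s in rng.integers(0, 19_000, 500)]
        peaks_b = [peak("chr1", int(s), int(s + rng.integers(50, 400)))
                   for s in rng.integers(0, 19_000, 500)]
        cands = merge_candidate_regions(peaks_a, peaks_b)
        member = np.zeros(20_000, dtype=bool)
        for p in peaks_a + peaks_b:
            member[p.interval.start:p.interval.end] = True
        from_cands = np.zeros(20_000, dtype=bool)
        for c in cands:
            from_cands[c.start:c.end] = True
        np.testing.assert_array_equal(member, from_cands)
        # candidates pairwise disjoint and sorted
        for a, b in zip(cands, cands[1:]):
            assert a.end < b.start


class TestChisq:
    def test_identical_proportions_give_zero(self):
        chi2, p = chisq_test(ContingencyTable2x2(10, 990, 10, 990))
        assert chi2 == 0.0 and p == 1.0

    def test_worked_example_against_yates_oracle(self):
        table = ContingencyTable2x2(10, 990, 40, 960)
        chi2, p = chisq_test(table)
        ref_chi2, ref_p, _, _ = chi2_contingency(
            [[10, 990], [40, 960]], correction=True)
        assert chi2 == pytest.approx(ref_chi2, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-12)
        assert chi2 == pytest.approx(17.25, abs=0.05)
        assert p == pytest.approx(3.3e-5, rel=0.05)

    def test_row_swap_symmetry(self):
        t1 = chisq_test(ContingencyTable2x2(10, 990, 40, 960))
        t2 = chisq_test(ContingencyTable2x2(40, 960, 10, 990))
        assert t1 == t2

    def test_thousand_random_tables_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 500, 4)
            if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            chi2, p = chisq_test(ContingencyTable2x2(int(a), int(b), int(c),
                                                     int(d)))
            ref = chi2_contingency([[a, b], [c, d]], correction=True)
            assert chi2 == pytest.approx(ref[0], rel=1e-9, abs=1e-9)
            assert p == pytest.approx(ref[1], rel=1e-9, abs=1e-12)

    def test_negative_entries_raise(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 5, 5, 5)

    def test_degenerate_margin_is_null(self):
        chi2, p = chisq_test(ContingencyTable2x2(0, 990, 0, 960))
        assert chi2 == 0.0 and p == 1.0


class TestBH:
    def test_matches_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=0, rtol=1e-12)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 200))
            np.testing.assert_array_equal(bh_adjust(p), bh_oracle(p))

    def test_q_never_below_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        assert np.all(bh_adjust(p) >= p)


class TestCallDmrs:
    def _samples(self, a, c, urc=10_000, region=(1000, 2000)):
        """Control with ``a`` and case with ``c`` reads in the region; the
        rest uniform elsewhere."""
        def build(k):
            rng = np.random.default_rng(0)
            inside = rng.integers(region[0], region[1], k)
            outside = rng.integers(10_000, 1_000_000, urc - k)
            mids = np.sort(np.concatenate([inside, outside]))
            return AlignedReadSet("s", {"chr1": np.column_stack(
                [mids, mids + 2])}, urc=urc)
        return build(a), build(c)

    def test_fold_gate_excludes_sub_twofold_changes(self):
        ctrl, case = self._samples(1000, 1900)
        cand = [GenomicInterval("chr1", 1000, 2000)]
        assert call_dmrs(cand, ctrl, case) == []
        # same candidate passes without the fold gate
        assert len(call_dmrs(cand, ctrl, case, min_fold=1.5)) == 1

    def test_direction_follows_fold(self):
        ctrl, case = self._samples(100, 450)
        (d,) = call_dmrs([GenomicInterval("chr1", 1000, 2000)], ctrl, case)
        assert d.direction == "hyper"
        assert d.fold == pytest.approx(4.5, rel=0.01)
        (d2,) = call_dmrs([GenomicInterval("chr1", 1000, 2000)], case, ctrl)
        assert d2.direction == "hypo"

    def test_zero_read_candidates_are_dropped(self):
        ctrl, case = self._samples(100, 400)
        dmrs = call_dmrs([GenomicInterval("chr1", 1000, 2000),
                          GenomicInterval("chr1", 5_000_000, 5_001_000)],
                         ctrl, case)
        assert len(dmrs) == 1

    def test_tightening_filters_shrinks_the_set(self, dataset, control_peaks,
                                                case_peaks):
        cands = merge_candidate_regions(control_peaks, case_peaks)
        loose = call_dmrs(cands, dataset.control, dataset.cases[0],
                          q_max=0.05, min_fold=2)
        tighter_fold = call_dmrs(cands, dataset.control, dataset.cases[0],
                                 q_max=0.05, min_fold=3)
        tighter_q = call_dmrs(cands, dataset.control, dataset.cases[0],
                              q_max=0.005, min_fold=2)
        loose_keys = {(d.interval.chrom, d.interval.start) for d in loose}
        assert {(d.interval.chrom, d.interval.start)
                for d in tighter_fold} <= loose_keys
        assert {(d.interval.chrom, d.interval.start)
                for d in tighter_q} <= loose_keys

    def test_planted_regions_recovered_with_direction(self, dataset,
                                                      control_peaks,
                                                      case_peaks):
        cands = merge_candidate_regions(control_peaks, case_peaks)
        dmrs = call_dmrs(cands, dataset.control, dataset.cases[0])
        planted = dataset.truth.planted
        hits = sum(
            1 for p in planted
            if any(d.direction == p.direction and
                   d.interval.overlaps(p.interval) for d in dmrs)
        )
        assert hits / len(planted) >= 0.85


class TestUltraDmrs:
    sizes = {"chr1": 10_000}

    def test_majority_support_emits_ultra(self):
        # hyper DMR overlapping segment [500,1000) by 300 bp in 4 of 6
        per_sample = [[make_dmr("chr1", 600, 900, "hyper")]] * 4 + [[], []]
        ultras = ultra_dmrs(per_sample, self.sizes)
        assert len(ultras) == 1
        u = ultras[0]
        assert (u.segment.start, u.segment.end) == (500, 1000)
        assert u.direction == "hyper" and u.support == 4

    def test_half_support_is_not_enough(self):
        per_sample = [[make_dmr("chr1", 600, 900, "hyper")]] * 3 + [[]] * 3
        assert ultra_dmrs(per_sample, self.sizes) == []

    def test_exactly_250bp_overlap_does_not_count(self):
        # DMR [500, 750) overlaps segment [500,1000) by exactly 250 bp
        per_sample = [[make_dmr("chr1", 500, 750, "hyper")]] * 6
        assert ultra_dmrs(per_sample, self.sizes) == []
        # one extra bp crosses the strict threshold
        per_sample = [[make_dmr("chr1", 500, 751, "hyper")]] * 6
        assert len(ultra_dmrs(per_sample, self.sizes)) == 1

    def test_conflicting_directions_drop_segment(self):
        per_sample = (
            [[make_dmr("chr1", 500, 1000, "hyper")]] * 4
            + [[make_dmr("chr1", 500, 1000, "hypo")]] * 4
        )
        assert ultra_dmrs(per_sample, self.sizes) == []

    def test_three_sample_majority_is_two(self):
        per_sample = [[make_dmr("chr1", 600, 950, "hypo")]] * 2 + [[]]
        ultras = ultra_dmrs(per_sample, self.sizes)
        assert len(ultras) == 1 and ultras[0].support == 2

    def test_long_dmr_spans_multiple_segments(self):
        per_sample = [[make_dmr("chr1", 0, 2000, "hyper")]] * 4 + [[]] * 2
        ultras = ultra_dmrs(per_sample, self.sizes)
        assert [(u.segment.start, u.segment.end) for u in ultras] == \
            [(0, 500), (500, 1000), (1000, 1500), (1500, 2000)]
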