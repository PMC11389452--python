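import numpy as np
import pytest

from bvcrkit.caller import (BivalentRegion, assign_dominance, call_bvcr,
                            chi_square_homogeneity, compare_prevalence,
                            dominance_frequency_table, flag_survivin,
                            merge_connected)
from bvcrkit.genomic_io import H3_MARKS, GenomicInterval, Peak
from bvcrkit.simulate import SynthConfig, simulate_peak_landscape

from conftest import per_base_components, random_peaks


def mkpeak(chrom, start, end, mark="other", tags=1.0):
    return Peak(GenomicInterval(chrom, start, end), mark,
                raw_tags=tags, norm_tags=tags, score=tags)


class TestMergeConnected:
    def test_one_bp_overlap_merges(self):
        fps = merge_connected([[mkpeak("chr1", 0, 10)], [mkpeak("chr1", 9, 20)]])
        assert len(fps) == 1
        assert fps[0][0] == GenomicInterval("chr1", 0, 20)

    def test_half_open_adjacency_does_not_merge(self):
        fps = merge_connected([[mkpeak("chr1", 0, 10)], [mkpeak("chr1", 10, 20)]])
        assert len(fps) == 2

    def test_different_chromosomes_never_merge(self):
        fps = merge_connected([[mkpeak("chr1", 0, 10)], [mkpeak("chr2", 0, 10)]])
        assert len(fps) == 2

    def test_members_grouped_by_mark(self):
        fps = merge_connected([[mkpeak("c", 0, 10, "H3K4me3")],
                               [mkpeak("c", 5, 15, "H3K27me3")]])
        (iv, members), = fps
        assert set(members) == {"H3K4me3", "H3K27me3"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng, 200, genome_len=50_000)
        got = {(fp[0].start, fp[0].end,
                frozenset(p for ps in fp[1].values() for p in ps))
               for fp in merge_connected([peaks])}
        want = {(s, e, members) for (s, e), members in
                per_base_components(peaks, 50_000)}
        assert got == want


class TestCallBvcr:
    def make_footprint_peaks(self):
        k4 = [mkpeak("c", 0, 100, "H3K4me3", 60)]
        k27me3 = [mkpeak("c", 50, 150, "H3K27me3", 30)]
        return k4, k27me3

    def test_missing_required_mark_excluded(self):
        k4, k27me3 = self.make_footprint_peaks()
        assert call_bvcr(k4, k27me3, []) == []

    def test_two_mark_mode_includes(self):
        k4, k27me3 = self.make_footprint_peaks()
        regions = call_bvcr(k4, k27me3, [],
                            required_marks={"H3K4me3", "H3K27me3"})
        assert len(regions) == 1
        assert regions[0].interval == GenomicInterval("c", 0, 150)

    def test_empty_required_marks_is_error(self):
        with pytest.raises(ValueError):
            call_bvcr([], [], [], required_marks=set())

    def test_tag_sums_and_pcts(self):
        k4 = [mkpeak("c", 0, 100, "H3K4me3", 60)]
        k27me3 = [mkpeak("c", 50, 150, "H3K27me3", 30)]
        k27ac = [mkpeak("c", 80, 120, "H3K27ac", 10)]
        (r,) = call_bvcr(k4, k27me3, k27ac)
        assert r.tag_sum == {"H3K4me3": 60, "H3K27me3": 30, "H3K27ac": 10}
        assert r.tag_pct["H3K4me3"] == pytest.approx(60.0)
        assert sum(r.tag_pct.values()) == pytest.approx(100.0)
        assert r.dominant == "H3K4me3" and not r.tie_flag

    def test_planted_loci_recovered_exactly_among_decoys(self):
        cfg = SynthConfig(seed=5, n_bvcr=600, n_decoys_per_mark=134,
                          n_survivin_decoys=0)
        peaks, truth = simulate_peak_landscape(cfg)
        regions = call_bvcr(peaks["H3K4me3"], peaks["H3K27me3"], peaks["H3K27ac"])
        assert len(regions) == 600
        # every call matches a planted locus footprint
        called = {(r.interval.chrom, r.interval.start) for r in regions}
        assert len(called) == 600


class TestAssignDominance:
    def make_region(self, k4, k27me3, k27ac):
        r = BivalentRegion(interval=GenomicInterval("c", 0, 10))
        r.tag_sum = {"H3K4me3": k4, "H3K27me3": k27me3, "H3K27ac": k27ac}
        return assign_dominance(r)

    def test_plain_argmax(self):
        r = self.make_region(60, 30, 10)
        assert r.dominant == "H3K4me3"
        assert [r.tag_pct[m] for m in H3_MARKS] == pytest.approx([60, 30, 10])
        assert not r.tie_flag

    def test_tie_breaks_by_priority_with_flag(self):
        r = self.make_region(50, 50, 0)
        assert r.dominant == "H3K4me3" and r.tie_flag

    def test_zero_tags_undefined(self):
        r = self.make_region(0, 0, 0)
        assert r.dominant is None and r.tag_pct == {}

    def test_argmax_matches_exhaustive_comparison(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tags = rng.integers(0, 100, size=3)
            if tags.sum() == 0:
                continue
            r = self.make_region(*tags)
            best = max(tags)
            # oracle: first mark (in priority order) attaining the max
            want = [m for m, t in zip(H3_MARKS, tags) if t == best][0]
            assert r.dominant == want
            assert r.tag_pct[r.dominant] == max(r.tag_pct.values())


class TestFlagSurvivin:
    def region(self, start, end):
        r = BivalentRegion(interval=GenomicInterval("c", start, end))
        r.region_id = "r0"
        return r

    def test_one_bp_overlap_positive(self):
        (r,) = flag_survivin([self.region(100, 200)],
                             [mkpeak("c", 199, 300, "survivin")])
        assert r.survivin_positive

    def test_adjacency_negative(self):
        (r,) = flag_survivin([self.region(100, 200)],
                             [mkpeak("c", 200, 300, "survivin")])
        assert not r.survivin_positive

    def test_monotone_under_added_peaks(self):
        rng = np.random.default_rng(1)
        regions = [self.region(i * 100, i * 100 + 50) for i in range(20)]
        few = random_peaks(rng, 5, genome_len=2_000, mark="survivin",
                           max_width=300)
        more = few + random_peaks(rng, 10, genome_len=2_000, mark="survivin",
                                  max_width=300)
        flags_few = [r.survivin_positive for r in flag_survivin(regions, few)]
        flags_more = [r.survivin_positive for r in flag_survivin(regions, more)]
        assert all(b or not a for a, b in zip(flags_few, flags_more))


class TestDominanceTable:
    def regions(self, spec):
        out = []
        for dominant, survivin, n in spec:
            for _ in range(n):
                r = BivalentRegion(interval=GenomicInterval("c", 0, 10))
                r.dominant = dominant
                r.survivin_positive = survivin
                out.append(r)
        return out

    def test_identical_distributions_give_p_one(self):
        regs = self.regions([("H3K4me3", False, 40), ("H3K27me3", False, 30),
                             ("H3K4me3", True, 40), ("H3K27me3", True, 30)])
        table, (stat, df, p) = dominance_frequency_table(regs)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # strata (100,0,0) vs (0,100,0): expected 50 in the two live
        # columns, contribution 50 per cell -> statistic 200, df 2
        stat, df, p = chi_square_homogeneity([[100, 0, 0], [0, 100, 0]])
        assert stat == pytest.approx(200.0)
        assert df == 2

    def test_counts_sum_to_stratum_size(self):
        regs = self.regions([("H3K4me3", False, 7), ("H3K27ac", True, 5)])
        table, _ = dominance_frequency_table(regs)
        counts = table[[f"count_{m}" for m in H3_MARKS]].sum(axis=1)
        assert (counts == table["n"]).all()

    def test_empty_stratum_skips_test(self):
        regs = self.regions([("H3K4me3", False, 5)])
        with pytest.warns(UserWarning, match="empty stratum"):
            table, result = dominance_frequency_table(regs)
        assert result is None and len(table) == 2


class TestComparePrevalence:
    def test_equal_proportions(self):
        z, p = compare_prevalence(10, 100, 10, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_formula_agreement(self):
        # independent evaluation of the pooled two-proportion z
        h1, n1, h2, n2 = 325, 4068, 205, 2131
        p1, p2, pp = h1 / n1, h2 / n2, (h1 + h2) / (n1 + n2)
        se = np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        z, _ = compare_prevalence(h1, n1, h2, n2)
        assert z == pytest.approx((p1 - p2) / se)
        assert abs(z) == pytest.approx(2.18, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_prevalence(1, 0, 1, 10)
        with pytest.raises(ValueError):
            compare_prevalence(11, 10, 1, 10)
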