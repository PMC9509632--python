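"""Interval arithmetic and enrichment statistics against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromstate.intervals import (
    ContingencyTable2x2,
    Genome,
    GenomicInterval,
    IntervalSet,
    chi_squared_2x2,
    classify_enhancers,
    fisher_exact_2x2,
    flatten,
    fold_enrichment_bp,
    hypergeom_upper_tail,
    intersect_bp,
    merge_nearby_regions,
    naive_overlap_peakset,
)
from chromstate.geneassoc import TSS

from conftest import coverage_mask, random_interval_set


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestFlatten:
    def test_overlapping_union(self):
        s = flatten(IntervalSet([iv(0, 10), iv(5, 20)]))
        assert s.intervals == [iv(0, 20)]

    def test_empty_identity(self):
        assert flatten(IntervalSet([])).intervals == []

    def test_abutting_merge(self):
        s = flatten(IntervalSet([iv(0, 10), iv(10, 20)]))
        assert s.intervals == [iv(0, 20)]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_covered_bp_matches_boolean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome = Genome({"chrT": 10_000})
        raw = random_interval_set(rng, genome, 50, max_len=500)
        flat = flatten(raw)
        oracle = int(coverage_mask(raw, genome)["chrT"].sum())
        assert flat.total_bp() == oracle
        # and flattening is idempotent / preserves coverage
        assert coverage_mask(flat, genome)["chrT"].sum() == oracle


class TestIntersectBp:
    def test_simple_overlap(self):
        a = IntervalSet([iv(0, 100)], flattened=True)
        b = IntervalSet([iv(50, 150)], flattened=True)
        assert intersect_bp(a, b) == 50

    def test_disjoint(self):
        a = IntervalSet([iv(0, 100)], flattened=True)
        b = IntervalSet([iv(200, 300)], flattened=True)
        assert intersect_bp(a, b) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_boolean_and_oracle(self, seed, toy_genome):
        rng = np.random.default_rng(100 + seed)
        a = flatten(random_interval_set(rng, toy_genome, 30))
        b = flatten(random_interval_set(rng, toy_genome, 40))
        ma, mb = coverage_mask(a, toy_genome), coverage_mask(b, toy_genome)
        oracle = sum(int((ma[c] & mb[c]).sum()) for c in ma)
        assert intersect_bp(a, b) == oracle


class TestFoldEnrichment:
    def test_identical_sets(self):
        g = Genome({"chr1": 1000})
        a = IntervalSet([iv(0, 100)], flattened=True)
        s = fold_enrichment_bp(a, a, g)
        assert s.observed == 100 and s.expected == 10 and s.fold == 10.0

    def test_disjoint_zero_fold(self):
        g = Genome({"chr1": 1000})
        a = IntervalSet([iv(0, 100)], flattened=True)
        b = IntervalSet([iv(500, 600)], flattened=True)
        assert fold_enrichment_bp(a, b, g).fold == 0.0

    def test_empty_set_sentinel(self):
        g = Genome({"chr1": 1000})
        a = IntervalSet([iv(0, 100)], flattened=True)
        s = fold_enrichment_bp(a, IntervalSet([], flattened=True), g)
        assert math.isnan(s.fold) and s.p == 1.0

    def test_self_enrichment_identity(self, toy_genome):
        rng = np.random.default_rng(7)
        a = flatten(random_interval_set(rng, toy_genome, 20))
        s = fold_enrichment_bp(a, a, toy_genome)
        assert s.fold == pytest.approx(toy_genome.total_bp / a.total_bp())

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_bp_oracle(self, seed, toy_genome):
        rng = np.random.default_rng(200 + seed)
        a = flatten(random_interval_set(rng, toy_genome, 20))
        b = flatten(random_interval_set(rng, toy_genome, 30))
        s = fold_enrichment_bp(a, b, toy_genome)
        ma, mb = coverage_mask(a, toy_genome), coverage_mask(b, toy_genome)
        obs = sum(int((ma[c] & mb[c]).sum()) for c in ma)
        na = sum(int(m.sum()) for m in ma.values())
        nb = sum(int(m.sum()) for m in mb.values())
        g = toy_genome.total_bp
        assert s.observed == obs
        assert s.fold == pytest.approx(obs / (na * nb / g))
        assert s.p == pytest.approx(float(stats.hypergeom.sf(obs - 1, g, nb, na)))


class TestHypergeomUpperTail:
    def test_tail_from_zero_is_one(self):
        assert hypergeom_upper_tail(0, 10, 5, 20) == 1.0

    def test_all_success_population(self):
        assert hypergeom_upper_tail(4, 4, 10, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # all C(10,4) draws from a 10-item population with 5 successes
        from itertools import combinations

        N, K, n, k = 10, 5, 4, 4
        draws = list(combinations(range(N), n))
        count = sum(1 for d in draws if sum(1 for x in d if x < K) >= k)
        assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(count / len(draws))

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 5, 10)


def fisher_two_sided_oracle(a, b, c, d):
    """Margin-fixed enumeration with point-probability ordering."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, n - (N - K)), min(K, n)
    probs = {
        x: math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_independence(self):
        s = fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert s.odds_ratio == 1.0 and s.p == pytest.approx(1.0)

    def test_zero_denominator_sentinel(self):
        s = fisher_exact_2x2(ContingencyTable2x2(5, 0, 2, 3))
        assert s.odds_ratio == float("inf")

    def test_both_zero_sentinel(self):
        s = fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 3))
        assert math.isnan(s.odds_ratio)

    def test_oracle_and_scipy_agreement(self):
        s = fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3))
        assert s.odds_ratio == 9.0
        assert s.p == pytest.approx(fisher_two_sided_oracle(3, 1, 1, 3))
        assert s.p == pytest.approx(
            float(stats.fisher_exact([[3, 1], [1, 3]])[1])
        )

    @given(
        st.tuples(
            st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        s = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert s.p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    @given(
        st.tuples(
            st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_row_swap_inverts_odds_ratio(self, cells):
        a, b, c, d = cells
        s1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        s2 = fisher_exact_2x2(ContingencyTable2x2(c, d, a, b))
        assert s2.p == pytest.approx(s1.p, abs=1e-12)
        if np.isfinite(s1.odds_ratio) and s1.odds_ratio > 0:
            assert s2.odds_ratio == pytest.approx(1 / s1.odds_ratio)


class TestChiSquared:
    def test_independence_zero(self):
        stat, p = chi_squared_2x2(ContingencyTable2x2(25, 25, 25, 25))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_zero_margin_sentinel(self):
        stat, p = chi_squared_2x2(ContingencyTable2x2(5, 5, 0, 0))
        assert math.isnan(stat) and p == 1.0

    @pytest.mark.parametrize(
        "cells", [(50, 0, 0, 50), (3, 7, 11, 2), (1, 2, 3, 4), (10, 1, 1, 10)]
    )
    def test_closed_form(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        expected = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        stat, p = chi_squared_2x2(ContingencyTable2x2(a, b, c, d))
        assert stat == pytest.approx(expected)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 1)))


class TestNaiveOverlapPeakset:
    def test_identical_peak_retained(self):
        pooled = IntervalSet([iv(0, 100)])
        reps = [IntervalSet([iv(0, 100)]), IntervalSet([iv(0, 100)])]
        assert len(naive_overlap_peakset(pooled, reps)) == 1

    def test_49_percent_dropped(self):
        pooled = IntervalSet([iv(0, 100)])
        assert len(naive_overlap_peakset(pooled, [IntervalSet([iv(0, 49)])])) == 0

    def test_exactly_half_retained(self):
        pooled = IntervalSet([iv(0, 100)])
        reps = [IntervalSet([iv(0, 50)]), IntervalSet([iv(25, 75)])]
        assert len(naive_overlap_peakset(pooled, reps)) == 1

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            naive_overlap_peakset(IntervalSet([iv(0, 10)]), [])

    def test_monotone_filtering(self, toy_genome):
        rng = np.random.default_rng(11)
        pooled = flatten(random_interval_set(rng, toy_genome, 30))
        reps = [flatten(random_interval_set(rng, toy_genome, 40)) for _ in range(3)]
        prev = pooled
        for i in range(1, 4):
            cur = naive_overlap_peakset(pooled, reps[:i])
            assert set(cur.intervals) <= set(prev.intervals)
            prev = cur

    def test_matches_coverage_oracle(self, toy_genome):
        rng = np.random.default_rng(13)
        pooled = flatten(random_interval_set(rng, toy_genome, 40))
        reps = [flatten(random_interval_set(rng, toy_genome, 50)) for _ in range(2)]
        got = set(naive_overlap_peakset(pooled, reps).intervals)
        masks = [coverage_mask(r, toy_genome) for r in reps]
        for peak in pooled:
            keep = all(
                m[peak.chrom][peak.start : peak.end].sum() >= 0.5 * len(peak)
                for m in masks
            )
            assert (peak in got) == keep


def merge_oracle(regions, ps, max_gap, max_width):
    """Direct restatement of the greedy chaining rule."""
    out = []
    for r, p in zip(regions, ps):
        if (
            out
            and out[-1][0] == r.chrom
            and r.start - out[-1][2] <= max_gap
            and max(r.end, out[-1][2]) - out[-1][1] <= max_width
        ):
            out[-1][2] = max(r.end, out[-1][2])
            out[-1][3] = min(out[-1][3], p)
        else:
            out.append([r.chrom, r.start, r.end, p])
    return out


class TestMergeNearbyRegions:
    def test_single_region_unchanged(self):
        merged, p, members = merge_nearby_regions(IntervalSet([iv(0, 100)]), [0.01])
        assert merged.intervals == [iv(0, 100)] and p[0] == 0.01

    def test_gap_exactly_500_merges(self):
        merged, p, _ = merge_nearby_regions(
            IntervalSet([iv(0, 100), iv(600, 700)]), [0.5, 0.01]
        )
        assert merged.intervals == [iv(0, 700)] and p[0] == 0.01

    def test_width_cap_blocks_extension(self):
        merged, _, _ = merge_nearby_regions(
            IntervalSet([iv(0, 4800), iv(4900, 5400)]), [0.5, 0.5]
        )
        assert len(merged) == 2  # merged width would be 5400 > 5000

    def test_oversized_region_passes_through(self):
        merged, _, _ = merge_nearby_regions(IntervalSet([iv(0, 8000)]), [0.5])
        assert merged.intervals == [iv(0, 8000)]

    def test_worked_chain(self):
        merged, p, _ = merge_nearby_regions(
            IntervalSet([iv(0, 100), iv(550, 650), iv(700, 800)]),
            [0.04, 0.001, 0.2],
        )
        # gap 100->550 is 450 <= 500 so first two merge; 650->700 gap 50 merges
        # too since the chained width stays <= 5000: full chain [0,800)
        assert merged.intervals == [iv(0, 800)]
        assert p[0] == 0.001

    def test_p_count_mismatch(self):
        with pytest.raises(ValueError):
            merge_nearby_regions(IntervalSet([iv(0, 10)]), [0.1, 0.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        starts = np.cumsum(rng.integers(50, 1500, size=40))
        regions = [iv(int(s), int(s + rng.integers(50, 800))) for s in starts]
        regions = [r for r in regions if r.start < r.end]
        # enforce sorted non-decreasing starts (allow overlaps)
        ps = rng.random(len(regions))
        merged, rep, _ = merge_nearby_regions(IntervalSet(regions), ps)
        oracle = merge_oracle(sorted(regions), ps, 500, 5000)
        assert [(m.chrom, m.start, m.end) for m in merged] == [
            (o[0], o[1], o[2]) for o in oracle
        ]
        assert np.allclose(rep, [o[3] for o in oracle])


class TestClassifyEnhancers:
    def setup_method(self):
        self.tss = [TSS("g1", "chr1", 50_000)]
        self.atac = IntervalSet([iv(0, 100_000)], flattened=True)
        self.se = IntervalSet([iv(90_000, 95_000)], flattened=True)

    def test_peak_on_tss_is_promoter_proximal(self):
        labels = classify_enhancers(
            IntervalSet([iv(49_900, 50_100)]), self.atac, self.se, self.tss
        )
        assert labels == ["promoter_proximal"]

    def test_distance_boundary(self):
        # nearest edge exactly 3001 bp from the TSS point -> typical enhancer
        peak_far = IntervalSet([iv(53_001, 53_500)])
        assert classify_enhancers(peak_far, self.atac, self.se, self.tss) == [
            "typical_enhancer"
        ]
        # exactly 3000 -> still promoter-proximal (inclusive boundary)
        peak_edge = IntervalSet([iv(53_000, 53_500)])
        assert classify_enhancers(peak_edge, self.atac, self.se, self.tss) == [
            "promoter_proximal"
        ]

    def test_super_enhancer_constituent(self):
        peak = IntervalSet([iv(91_000, 92_000)])
        assert classify_enhancers(peak, self.atac, self.se, self.tss) == [
            "super_enhancer_constituent"
        ]

    def test_no_atac_is_other(self):
        peak = IntervalSet([iv(70_000, 71_000)])
        no_atac = IntervalSet([], flattened=True)
        assert classify_enhancers(peak, no_atac, self.se, self.tss) == ["other"]
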