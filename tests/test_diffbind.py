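"""Differential occupancy: normalization, testing, merging, FDR."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from chromstate.diffbind import (
    DifferentialAbundance,
    RegionCountMatrix,
    build_consensus,
    filter_low_abundance,
    log2_cpm,
    loess_offsets,
    merge_and_adjust,
)
from chromstate.diffbind import test_differential as run_differential_test
from chromstate.intervals import GenomicInterval, IntervalSet
from chromstate.synthetic import SyntheticScenario, simulate_counts

from conftest import coverage_mask, random_interval_set


def region_matrix(counts, conditions=("a", "a", "b", "b"), lib=None, spacing=10_000):
    counts = np.asarray(counts)
    regions = IntervalSet(
        [
            GenomicInterval("chrS", i * spacing, i * spacing + 1000)
            for i in range(counts.shape[0])
        ],
        flattened=True,
    )
    lib = np.full(counts.shape[1], 1e6) if lib is None else np.asarray(lib, float)
    return RegionCountMatrix(regions, counts, list(conditions), lib)


class TestBuildConsensus:
    def test_identical_sets(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100)], flattened=True)
        assert build_consensus([s, s]) == s

    def test_union_matches_boolean_oracle(self, toy_genome):
        rng = np.random.default_rng(0)
        sets = [random_interval_set(rng, toy_genome, 25) for _ in range(3)]
        consensus = build_consensus(sets)
        masks = [coverage_mask(s, toy_genome) for s in sets]
        for chrom in toy_genome.chrom_lengths:
            union = np.zeros(toy_genome.chrom_lengths[chrom], bool)
            for m in masks:
                union |= m[chrom]
            assert coverage_mask(consensus, toy_genome)[chrom].sum() == union.sum()
        assert consensus.flattened


class TestFilterLowAbundance:
    def test_all_zero_region_removed(self):
        # at IP-library scale the prior-count floor log2(2 / (L/1e6)) sits
        # well below -3, so an uncovered region is always filtered
        L = 48e6
        m = region_matrix(
            [[0, 0, 0, 0], [5000, 4800, 5100, 5050]], lib=np.full(4, L)
        )
        floor = log2_cpm(np.zeros((1, 4)), np.full(4, L)).mean()
        assert floor < -3
        assert filter_low_abundance(m).n_regions == 1

    def test_exact_boundary_retained(self):
        # counts chosen so average log2CPM == -3 exactly with prior count 2,
        # equal library sizes: (y + 2) / (L + 4) * 1e6 = 2^-3 at y=4
        L = 48e6 - 4
        m = region_matrix(np.full((1, 4), 4), lib=np.full(4, L))
        avg = log2_cpm(m.counts, m.lib_size).mean()
        assert avg == pytest.approx(-3.0, abs=1e-12)
        assert filter_low_abundance(m).n_regions == 1
        # just below the boundary is removed
        m2 = region_matrix(np.full((1, 4), 3.999), lib=np.full(4, L))
        assert filter_low_abundance(m2).n_regions == 0

    def test_high_count_regions_kept(self):
        rng = np.random.default_rng(1)
        m = region_matrix(rng.poisson(500, size=(50, 4)))
        assert filter_low_abundance(m).n_regions == 50


class TestLoessOffsets:
    def test_identical_samples_zero_offsets(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(300, size=(500, 1))
        m = region_matrix(np.hstack([y, y]), conditions=("a", "b"))
        offs = loess_offsets(m)
        assert np.abs(offs).max() < 1e-8

    def test_four_fold_scaling_gives_log2_four_gap(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(300, size=(600, 1))
        m = region_matrix(np.hstack([y, 4 * y]), conditions=("a", "b"))
        offs = loess_offsets(m)
        gap = offs[:, 1] - offs[:, 0]
        assert np.abs(gap - 2.0).max() < 0.05

    def test_recovers_planted_smooth_trend(self):
        rng = np.random.default_rng(4)
        base = rng.integers(50, 5000, size=(1500,))
        y0 = rng.poisson(base)
        a_proxy = np.log2(base / 1e6 * 1e6)
        trend = 0.3 * np.sin(a_proxy / 2) + 0.1 * a_proxy / 10
        y1 = rng.poisson(base * 2.0**trend)
        m = region_matrix(np.column_stack([y0, y1]), conditions=("a", "b"))
        offs = loess_offsets(m)
        gap = offs[:, 1] - offs[:, 0]
        rmse = np.sqrt(np.mean((gap - trend) ** 2))
        assert rmse < 0.1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            loess_offsets(region_matrix([[5], [10]], conditions=("a",)))


class TestTestDifferential:
    def test_identical_conditions_null_result(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(400, size=(200, 2))
        m = region_matrix(np.hstack([y, y]))
        tab = run_differential_test(m)
        assert np.abs(tab["log2fc"]).max() < 1e-6
        assert (tab["p"] > 0.99).all()

    def test_single_condition_rejected(self):
        m = region_matrix([[1, 2, 3, 4]], conditions=("a", "a", "a", "a"))
        with pytest.raises(ValueError):
            run_differential_test(m)

    def test_null_type_one_error_calibrated(self):
        # single-seed smoke of the calibration property (the full 20-seed
        # protocol lives in the acceptance suite)
        sc = SyntheticScenario(seed=11, planted_fraction=0.0)
        m, _ = simulate_counts(sc)
        tab = run_differential_test(m, loess_offsets(m))
        rate = (tab["p"] < 0.05).mean()
        assert 0.030 < rate < 0.070  # 99.9% binomial band for n=2000

    def test_planted_regions_detected_with_correct_sign(self):
        sc = SyntheticScenario(seed=12)
        m, true_fc = simulate_counts(sc)
        tab = run_differential_test(m, loess_offsets(m))
        _, fdr, _, _ = multipletests(tab["p"], method="fdr_bh")
        planted = true_fc != 0
        power = ((fdr < 0.05) & planted).sum() / planted.sum()
        assert power >= 0.9
        det = (fdr < 0.05) & planted
        assert (np.sign(tab["log2fc"][det]) == np.sign(true_fc[det])).all()

    def test_matches_edger_quasilikelihood(self, tmp_path):
        """Independent oracle: the same counts through edgeR's QL pipeline."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the edgeR cross-check")
        sc = SyntheticScenario(seed=42, n_regions=300)
        m, _ = simulate_counts(sc)
        np.savetxt(tmp_path / "counts.tsv", m.counts, fmt="%d", delimiter="\t")
        rscript = tmp_path / "check.R"
        rscript.write_text(
            'suppressMessages(library(edgeR))\n'
            'counts <- as.matrix(read.delim("counts.tsv", header=FALSE))\n'
            'group <- factor(c("A","A","B","B"))\n'
            f'y <- DGEList(counts=counts, lib.size=rep({sc.lib_size}, 4), group=group)\n'
            'design <- model.matrix(~group)\n'
            'y <- estimateDisp(y, design)\n'
            'fit <- glmQLFit(y, design)\n'
            'res <- glmQLFTest(fit, coef=2)\n'
            'write.table(data.frame(logFC=res$table$logFC, p=res$table$PValue),\n'
            '            "edger.tsv", sep="\\t", row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", rscript.name], cwd=tmp_path, check=True, capture_output=True
        )
        r = pd.read_csv(tmp_path / "edger.tsv", sep="\t")
        tab = run_differential_test(m, None)
        assert np.abs(tab["log2fc"].to_numpy() - r["logFC"].to_numpy()).max() < 0.01
        rank_corr = pd.Series(tab["p"]).corr(r["p"], method="spearman")
        assert rank_corr > 0.99


class TestMergeAndAdjust:
    def test_isolated_regions_plain_bh(self):
        rng = np.random.default_rng(6)
        regions = IntervalSet(
            [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(100)],
            flattened=True,
        )
        ps = rng.random(100)
        fcs = rng.normal(size=100)
        results = merge_and_adjust(regions, ps, fcs)
        assert len(results) == 100
        # BH oracle: sort, cumulative minimum from the right
        order = np.argsort(ps)
        bh = np.empty(100)
        prev = 1.0
        for rank in range(99, -1, -1):
            i = order[rank]
            prev = min(prev, ps[i] * 100 / (rank + 1))
            bh[i] = prev
        got = np.array([r.fdr for r in results])
        assert np.allclose(got, bh)

    def test_single_block_min_p(self):
        regions = IntervalSet(
            [GenomicInterval("chr1", i * 600, i * 600 + 400) for i in range(4)],
            flattened=True,
        )
        results = merge_and_adjust(regions, [0.3, 0.01, 0.2, 0.5], [1, -2, 1, 1])
        assert len(results) == 1
        r = results[0]
        assert r.p == 0.01 and r.fdr == 0.01
        assert r.log2fc == -2 and r.direction == "decreasing"

    def test_direction_stable_above_fdr(self):
        regions = IntervalSet([GenomicInterval("chr1", 0, 100)], flattened=True)
        (r,) = merge_and_adjust(regions, [0.5], [3.0])
        assert r.direction == "stable"


class TestDifferentialAbundanceEstimator:
    def test_end_to_end_counts_planted_directions(self):
        sc = SyntheticScenario(seed=13)
        m, true_fc = simulate_counts(sc)
        est = DifferentialAbundance().fit(m)
        frame = est.results_frame()
        n_sig = (frame["direction"] != "stable").sum()
        n_planted = (true_fc != 0).sum()
        assert 0.85 * n_planted <= n_sig <= 1.15 * n_planted
        assert set(est.get_params()) >= {"min_avg_log2cpm", "span", "fdr"}

    def test_sklearn_param_interface(self):
        est = DifferentialAbundance(fdr=0.01)
        assert est.get_params()["fdr"] == 0.01
        est.set_params(fdr=0.1)
        assert est.fdr == 0.1
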