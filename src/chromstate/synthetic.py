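"""Synthetic data with recorded ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* 200-bp binned, two-condition chromatin signal driven by a hidden Markov
  state path with per-state, per-feature Bernoulli presence and Poisson
  read counts, plus uniform Poisson control tracks;
* factor peak catalogs with planted per-site odds ratios against a
  positive/negative partition of target sites;
* negative-binomial region count matrices with planted log2 fold-changes.

Everything is a pure function of (scenario, seed); truth objects are
returned alongside the data so recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binarize import BinnedTrack
from .diffbind import RegionCountMatrix
from .intervals import Genome, GenomicInterval, IntervalSet
from .screen import FactorCatalog
from .statemodel import EmissionModel, Segmentation

__all__ = [
    "SyntheticScenario",
    "simulate_chromatin",
    "simulate_factor_catalog",
    "simulate_counts",
    "default_emission_matrix",
]

CONDITION_A = "control"
CONDITION_B = "depleted"


def default_emission_matrix(n_states: int, n_features: int, seed: int = 7) -> np.ndarray:
    """A well-separated, sparse Bernoulli emission matrix for simulation truth.

    Each state strongly emits one feature (two for states beyond the feature
    count, keeping patterns distinct) over a low background (0.01-0.05).
    Sparse marks mirror real chromatin, where any one feature covers a small
    genomic fraction and most bins are quiescent for it.
    """
    rng = np.random.default_rng(seed)
    e = rng.uniform(0.01, 0.05, size=(n_states, n_features))
    for k in range(n_states):
        e[k, k % n_features] = rng.uniform(0.75, 0.95)
        if k >= n_features:
            # offset partner keeps every feature active in <= 2 states, so no
            # single mark dominates the genome-wide background rate
            e[k, (k + 2) % n_features] = rng.uniform(0.6, 0.9)
    return e


@dataclass
class SyntheticScenario:
    """Study-scale defaults for all generators.

    The genome is 3 chromosomes of 1 Mb at 200-bp bins; chromatin states
    persist ~20 bins (4 kb, enhancer/domain scale) with ~5% of bins
    switching state between conditions in contiguous blocks (mean 10 bins,
    enhancer-scale changes). Read depth is 40 per present bin over a 0.2
    background — IP-library scale for 200-bp bins — so presence is
    recoverable by the Poisson binarization. Count matrices default to a
    typical differential ChIP design:
    2 vs 2 samples, 2,000 regions, NB dispersion 0.05, 1e6 library size.
    """

    genome: Genome = field(
        default_factory=lambda: Genome({"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000})
    )
    bin_size: int = 200
    n_states: int = 8
    n_features: int = 6
    emission: np.ndarray | None = None  # default built from (n_states, n_features)
    mean_dwell: float = 20.0
    depth: float = 40.0
    background: float = 0.2
    control_depth: float = 5.0  # input libraries are deeply, uniformly covered
    diff_state_fraction: float = 0.05
    diff_block_bins: float = 10.0
    feature_names: list[str] | None = None
    # factor-catalog simulation
    n_factors: int = 20
    base_overlap: float = 0.1
    # count simulation
    n_regions: int = 2000
    n_replicates: int = 2
    planted_log2fc: float = 2.0
    planted_fraction: float = 0.1
    dispersion: float = 0.05
    lib_size: float = 1e6
    seed: int = 0

    def resolved_emission(self) -> np.ndarray:
        if self.emission is not None:
            e = np.asarray(self.emission, dtype=float)
            if e.shape != (self.n_states, self.n_features):
                raise ValueError("emission matrix shape mismatch")
            return e
        return default_emission_matrix(self.n_states, self.n_features)

    def resolved_features(self) -> list[str]:
        if self.feature_names is not None:
            if len(self.feature_names) != self.n_features:
                raise ValueError("feature_names length mismatch")
            return list(self.feature_names)
        return [f"feat{i + 1}" for i in range(self.n_features)]


def _markov_path(
    n_bins: int, n_states: int, mean_dwell: float, rng: np.random.Generator
) -> np.ndarray:
    """State path with self-transition 1 - 1/mean_dwell, uniform otherwise."""
    stay = 1.0 - 1.0 / mean_dwell
    path = np.empty(n_bins, dtype=np.int64)
    path[0] = rng.integers(n_states)
    switches = rng.random(n_bins - 1) >= stay
    jumps = rng.integers(1, n_states, size=n_bins - 1)  # offset avoids self
    for t in range(1, n_bins):
        if switches[t - 1]:
            path[t] = (path[t - 1] + jumps[t - 1]) % n_states
        else:
            path[t] = path[t - 1]
    return path


def _plant_switches(
    path: np.ndarray,
    fraction: float,
    block_bins: float,
    n_states: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reassign contiguous blocks (geometric length) to new random states."""
    out = path.copy()
    target = int(round(fraction * len(path)))
    changed = 0
    while changed < target:
        start = int(rng.integers(len(path)))
        length = int(rng.geometric(1.0 / block_bins))  # mean = block_bins
        end = min(start + length, len(path), start + (target - changed))
        new_state = (out[start] + int(rng.integers(1, n_states))) % n_states
        out[start:end] = new_state
        changed += end - start
    return out


def simulate_chromatin(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[
    dict[tuple[str, str], BinnedTrack],
    dict[str, BinnedTrack],
    Segmentation,
    EmissionModel,
]:
    """Generate two-condition binned count tracks from a hidden state path.

    Returns ``(tracks, controls, truth_segmentation, truth_model)`` where
    ``tracks`` is keyed by (condition, feature), ``controls`` by condition.
    Counts are Poisson(depth) on present bins plus Poisson(background)
    everywhere; presence is Bernoulli from the true emission matrix; the
    second condition reuses the first's path except in planted contiguous
    switch blocks covering ``diff_state_fraction`` of bins.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    e_true = scenario.resolved_emission()
    features = scenario.resolved_features()
    k, f = scenario.n_states, scenario.n_features
    paths: dict[tuple[str, str], np.ndarray] = {}
    tracks: dict[tuple[str, str], BinnedTrack] = {}
    ctrl_values: dict[str, dict[str, np.ndarray]] = {CONDITION_A: {}, CONDITION_B: {}}
    feat_values: dict[tuple[str, str], dict[str, np.ndarray]] = {
        (cond, feat): {} for cond in (CONDITION_A, CONDITION_B) for feat in features
    }
    for chrom, length in scenario.genome.chrom_lengths.items():
        n_bins = -(-length // scenario.bin_size)
        path_a = _markov_path(n_bins, k, scenario.mean_dwell, rng)
        if scenario.diff_state_fraction > 0:
            path_b = _plant_switches(
                path_a, scenario.diff_state_fraction, scenario.diff_block_bins, k, rng
            )
        else:
            path_b = path_a.copy()
        paths[(CONDITION_A, chrom)] = path_a + 1
        paths[(CONDITION_B, chrom)] = path_b + 1
        for cond, path in ((CONDITION_A, path_a), (CONDITION_B, path_b)):
            for j, feat in enumerate(features):
                present = rng.random(n_bins) < e_true[path, j]
                counts = rng.poisson(scenario.background, size=n_bins).astype(float)
                counts[present] += rng.poisson(scenario.depth, size=int(present.sum()))
                feat_values[(cond, feat)][chrom] = counts
            ctrl_values[cond][chrom] = rng.poisson(
                scenario.control_depth, size=n_bins
            ).astype(float)
    for (cond, feat), values in feat_values.items():
        tracks[(cond, feat)] = BinnedTrack(
            feature=feat, condition=cond, bin_size=scenario.bin_size, values=values
        )
    controls = {
        cond: BinnedTrack(
            feature="control", condition=cond, bin_size=scenario.bin_size, values=vals
        )
        for cond, vals in ctrl_values.items()
    }
    truth_seg = Segmentation(states=paths, n_states=k, bin_size=scenario.bin_size)
    truth_model = EmissionModel(
        emission=e_true,
        transition=_true_transition(k, scenario.mean_dwell),
        start=np.full(k, 1.0 / k),
        feature_names=features,
        bin_size=scenario.bin_size,
    )
    return tracks, controls, truth_seg, truth_model


def _true_transition(n_states: int, mean_dwell: float) -> np.ndarray:
    stay = 1.0 - 1.0 / mean_dwell
    if n_states == 1:
        return np.ones((1, 1))
    a = np.full((n_states, n_states), (1.0 - stay) / (n_states - 1))
    np.fill_diagonal(a, stay)
    return a


def simulate_factor_catalog(
    scenario: SyntheticScenario,
    positive: IntervalSet,
    negative: IntervalSet,
    planted_or: dict[str, float] | None = None,
    seed: int | None = None,
) -> tuple[FactorCatalog, dict[str, float], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Factor peak sets with planted site-level odds ratios.

    Negative sites are overlapped with the base probability p0 =
    ``scenario.base_overlap``; positive sites with p1 such that the odds
    ratio [p1/(1-p1)] / [p0/(1-p0)] equals the planted OR. Factor peaks are
    placed inside overlapped sites (the central half of each site). Returns
    the catalog, the planted ORs, and the per-class membership masks.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    p0 = scenario.base_overlap
    if not (0 < p0 < 1):
        raise ValueError("base_overlap must be in (0, 1)")
    if planted_or is None:
        planted_or = {
            f"factor{i + 1:03d}": float(v)
            for i, v in enumerate(
                rng.choice([0.5, 1.0, 2.0, 3.0], size=scenario.n_factors)
            )
        }
    factors: dict[str, IntervalSet] = {}
    memberships: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pos_sites = list(positive)
    neg_sites = list(negative)
    for name, or_true in planted_or.items():
        if or_true == float("inf"):
            p1 = 1.0
        else:
            odds1 = or_true * p0 / (1 - p0)
            p1 = odds1 / (1 + odds1)
        if not (0 <= p1 <= 1):
            raise ValueError(f"planted OR {or_true} unattainable at base rate {p0}")
        mask_pos = rng.random(len(pos_sites)) < p1
        mask_neg = rng.random(len(neg_sites)) < p0
        peaks = [
            _central_subinterval(site)
            for site, hit in zip(pos_sites, mask_pos)
            if hit
        ] + [
            _central_subinterval(site)
            for site, hit in zip(neg_sites, mask_neg)
            if hit
        ]
        factors[name] = IntervalSet(peaks)
        memberships[name] = (mask_pos, mask_neg)
    return FactorCatalog(factors), dict(planted_or), memberships


def _central_subinterval(site: GenomicInterval) -> GenomicInterval:
    quarter = max(len(site) // 4, 0)
    start = site.start + quarter
    end = max(site.end - quarter, start + 1)
    return GenomicInterval(site.chrom, start, end)


def simulate_counts(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[RegionCountMatrix, np.ndarray]:
    """NB region count matrix with planted fold-changes in condition B.

    Region means are log-normal around ``lib_size / n_regions``; counts are
    negative binomial with the scenario's common dispersion. A random
    ``planted_fraction`` of regions receives ``planted_log2fc`` (alternating
    sign) in the second condition. Returns the matrix and the per-region
    true log2FC (0 for null regions).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    r = scenario.n_regions
    n_rep = scenario.n_replicates
    base = scenario.lib_size / r
    mu0 = base * np.exp(rng.normal(0.0, 0.7, size=r))
    true_fc = np.zeros(r)
    n_planted = int(round(scenario.planted_fraction * r))
    if n_planted and scenario.planted_log2fc != 0:
        idx = rng.choice(r, size=n_planted, replace=False)
        signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
        true_fc[idx] = scenario.planted_log2fc * signs
    conditions = [CONDITION_A] * n_rep + [CONDITION_B] * n_rep
    mu = np.column_stack(
        [mu0] * n_rep + [mu0 * 2.0**true_fc] * n_rep
    )
    alpha = scenario.dispersion
    if alpha > 0:
        # NB via Gamma-Poisson: shape 1/alpha, scale alpha*mu
        lam = rng.gamma(1.0 / alpha, alpha * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)
    # region boundaries: 1-kb regions spaced 10 kb apart along chr1-like axis
    regions = IntervalSet(
        [GenomicInterval("chrS", i * 10_000, i * 10_000 + 1_000) for i in range(r)],
        flattened=True,
    )
    lib = np.full(2 * n_rep, scenario.lib_size)
    return (
        RegionCountMatrix(
            regions=regions,
            counts=counts,
            sample_condition=conditions,
            lib_size=lib,
        ),
        true_fc,
    )
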