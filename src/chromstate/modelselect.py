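"""Quantitative choice of the chromatin-state count.

Models are fit over a range of state counts (commonly 5 to 40) and
compared against the most complex model by two criteria:

1. *Median maximal state correlation* — for each reference state, the best
   Pearson correlation between its emission row and any candidate state's
   row; summarized by the median over reference states. High values mean the
   candidate model retains the reference model's emission structure.
2. *k-means goodness of fit* — emission rows from all models in the series
   are pooled and clustered with k equal to the candidate's state count; the
   between-cluster over total sum-of-squares ratio measures how much of the
   pooled emission diversity k clusters explain.

The selected K* is the smallest state count where both criteria exceed the
threshold (default 0.95, strict inequality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .statemodel import EmissionModel

__all__ = [
    "ModelSeries",
    "StateCountSelector",
    "median_max_state_correlation",
    "kmeans_goodness",
    "select_optimal_states",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelSeries:
    """Fitted models over a range of state counts, sharing one feature set."""

    models: dict[int, EmissionModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("empty model series")
        feats = {tuple(m.feature_names) for m in self.models.values()}
        if len(feats) > 1:
            raise ValueError("models in a series must share the feature set")

    @property
    def reference_K(self) -> int:
        return max(self.models)

    @property
    def reference(self) -> EmissionModel:
        return self.models[self.reference_K]

    def pooled_emissions(self) -> np.ndarray:
        return np.vstack([self.models[k].emission for k in sorted(self.models)])


def _row_correlations(reference: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Pearson correlation of every reference row against every candidate row.

    Zero-variance rows correlate 0 with everything (logged, not NaN).
    """
    ref = reference - reference.mean(axis=1, keepdims=True)
    cand = candidate - candidate.mean(axis=1, keepdims=True)
    ref_norm = np.linalg.norm(ref, axis=1)
    cand_norm = np.linalg.norm(cand, axis=1)
    degenerate = (ref_norm == 0)[:, None] | (cand_norm == 0)[None, :]
    if degenerate.any():
        logger.warning("constant emission row(s): correlation defined as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ref @ cand.T) / np.outer(ref_norm, cand_norm)
    corr[degenerate] = 0.0
    return corr


def median_max_state_correlation(
    reference: EmissionModel, candidate: EmissionModel
) -> float:
    """Median over reference states of the best emission-row correlation."""
    if list(reference.feature_names) != list(candidate.feature_names):
        raise ValueError("models compare emission rows over the same features")
    corr = _row_correlations(reference.emission, candidate.emission)
    return float(np.median(corr.max(axis=1)))


def kmeans_goodness(series: ModelSeries, k: int, seed: int = 0) -> float:
    """Between-cluster / total sum-of-squares of k-means on pooled emissions.

    Rows from every model in the series are pooled; k-means (k-means++
    seeded, best of 10 restarts) partitions them and the explained-variance
    ratio 1 - within/total is returned (0 when k = 1, 1 when every distinct
    row is its own cluster).
    """
    pooled = series.pooled_emissions()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pooled):
        raise ValueError(f"k={k} exceeds the {len(pooled)} pooled emission rows")
    total_ss = float(((pooled - pooled.mean(axis=0)) ** 2).sum())
    if total_ss == 0:
        return 1.0
    if k == 1:
        return 0.0
    n_distinct = len(np.unique(pooled, axis=0))
    if k > n_distinct:
        k = n_distinct  # k-means cannot use more clusters than distinct rows
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pooled)
    within_ss = float(km.inertia_)
    return 1.0 - within_ss / total_ss


def criteria_table(series: ModelSeries, seed: int = 0) -> pd.DataFrame:
    """Per-K selection criteria for plotting the model-choice curve."""
    reference = series.reference
    rows = []
    for k in sorted(series.models):
        rows.append(
            {
                "K": k,
                "median_max_correlation": median_max_state_correlation(
                    reference, series.models[k]
                ),
                "kmeans_goodness": kmeans_goodness(series, k, seed=seed),
            }
        )
    return pd.DataFrame(rows)


def select_optimal_states(
    series: ModelSeries, threshold: float = 0.95, seed: int = 0
) -> int:
    """Smallest K where both criteria strictly exceed ``threshold``.

    Falls back to the largest K (with a warning) when no model qualifies.
    """
    table = criteria_table(series, seed=seed)
    ok = (table["median_max_correlation"] > threshold) & (
        table["kmeans_goodness"] > threshold
    )
    if ok.any():
        return int(table.loc[ok, "K"].min())
    logger.warning(
        "no model exceeds threshold %.3f on both criteria; returning K=%d",
        threshold,
        series.reference_K,
    )
    return series.reference_K


class StateCountSelector(BaseEstimator):
    """Estimator wrapper around the two-criterion state-count selection.

    ``fit`` takes a :class:`ModelSeries`; fitted attributes expose the
    selected count (``best_k_``) and the per-K criteria (``criteria_``).
    """

    def __init__(self, threshold: float = 0.95, seed: int = 0):
        self.threshold = threshold
        self.seed = seed

    def fit(self, series: ModelSeries) -> "StateCountSelector":
        self.criteria_ = criteria_table(series, seed=self.seed)
        ok = (self.criteria_["median_max_correlation"] > self.threshold) & (
            self.criteria_["kmeans_goodness"] > self.threshold
        )
        self.best_k_ = (
            int(self.criteria_.loc[ok, "K"].min()) if ok.any() else series.reference_K
        )
        return self
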