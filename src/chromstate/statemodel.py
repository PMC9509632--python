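"""Multivariate Bernoulli-emission hidden Markov chromatin-state model.

Binarized presence calls for F chromatin features at 200-bp bins are modeled
as emissions of a K-state HMM: state k emits feature f independently with
probability E[k, f]. The model is trained by Baum-Welch EM on both
conditions jointly ("concatenated"): every chromosome of every condition is
an independent emission sequence, and all sequences share one set of
parameters, so a state has the same meaning in both conditions and the
decoded segmentations are directly comparable.

The estimator follows scikit-learn conventions: construct with
hyper-parameters, ``fit`` on a list of (T_i, F) binary sequence arrays,
read fitted parameters from trailing-underscore attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .binarize import BinaryCalls
from .intervals import EnrichmentStat, Genome, IntervalSet, flatten, hypergeom_upper_tail

__all__ = [
    "EmissionModel",
    "Segmentation",
    "BernoulliHMM",
    "fit_hmm",
    "decode_states",
    "state_enrichment",
    "stack_calls",
]

EMISSION_CLAMP = 1e-6  # keep Bernoulli rates in [1e-6, 1 - 1e-6]


@dataclass
class EmissionModel:
    """Fitted K-state, F-feature Bernoulli HMM parameters."""

    emission: np.ndarray  # (K, F) Bernoulli success probabilities
    transition: np.ndarray  # (K, K) row-stochastic
    start: np.ndarray  # (K,) initial distribution
    feature_names: list[str]
    bin_size: int = 200
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        k = self.emission.shape[0]
        if self.transition.shape != (k, k) or self.start.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.start.sum(), 1.0, atol=1e-6):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def n_features(self) -> int:
        return self.emission.shape[1]

    def to_dict(self) -> dict:
        return {
            "K": self.n_states,
            "F": self.n_features,
            "E": self.emission.tolist(),
            "A": self.transition.tolist(),
            "pi": self.start.tolist(),
            "feature_names": list(self.feature_names),
            "bin_size": self.bin_size,
            "log_likelihood": self.log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EmissionModel":
        return cls(
            emission=np.asarray(d["E"]),
            transition=np.asarray(d["A"]),
            start=np.asarray(d["pi"]),
            feature_names=list(d["feature_names"]),
            bin_size=int(d.get("bin_size", 200)),
            log_likelihood=float(d.get("log_likelihood", float("nan"))),
        )


@dataclass
class Segmentation:
    """Decoded per-bin state labels (1..K), keyed by (condition, chrom)."""

    states: dict[tuple[str, str], np.ndarray]
    n_states: int
    bin_size: int = 200

    def __post_init__(self) -> None:
        for key, v in self.states.items():
            v = np.asarray(v, dtype=np.int64)
            if v.size and (v.min() < 1 or v.max() > self.n_states):
                raise ValueError(f"{key}: state labels outside 1..{self.n_states}")
            self.states[key] = v


def stack_calls(calls: Sequence[BinaryCalls]) -> tuple[dict[tuple[str, str], np.ndarray], list[str]]:
    """Bundle per-feature calls into (condition, chrom) -> (T, F) matrices.

    All features must share conditions, chromosomes, and bin counts.
    """
    if not calls:
        raise ValueError("no call tracks supplied")
    features = [c.feature for c in calls]
    by_cond: dict[str, list[BinaryCalls]] = {}
    for c in calls:
        by_cond.setdefault(c.condition, []).append(c)
    sequences: dict[tuple[str, str], np.ndarray] = {}
    for cond, tracks in sorted(by_cond.items()):
        chroms = sorted(tracks[0].calls)
        for t in tracks:
            if sorted(t.calls) != chroms:
                raise ValueError("features disagree on chromosomes")
        feat_order = sorted(range(len(tracks)), key=lambda i: features.index(tracks[i].feature))
        for chrom in chroms:
            mat = np.column_stack([tracks[i].calls[chrom] for i in feat_order])
            sequences[(cond, chrom)] = mat.astype(np.uint8)
    return sequences, sorted(set(features), key=features.index)


try:  # numba accelerates the per-bin recursions ~100x; fall back gracefully
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _fb_core(b, transition, start):  # pragma: no cover - exercised via wrapper
    T, K = b.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = start[k] * b[0, k]
        s += alpha[0, k]
    scale[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * transition[j, k]
            alpha[t, k] = acc * b[t, k]
            s += alpha[t, k]
        scale[t] = s
        for k in range(K):
            alpha[t, k] /= s
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += transition[j, k] * b[t + 1, k] * beta[t + 1, k]
            beta[t, j] = acc / scale[t + 1]
        for j in range(K):
            aj = alpha[t, j]
            for k in range(K):
                xi_sum[j, k] += (
                    aj * transition[j, k] * b[t + 1, k] * beta[t + 1, k] / scale[t + 1]
                )
    gamma = alpha * beta
    for t in range(T):
        s = 0.0
        for k in range(K):
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s
    return gamma, xi_sum, scale


def _forward_backward(
    log_b: np.ndarray, transition: np.ndarray, start: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Scaled forward-backward. Returns (gamma, xi_sum, loglik, scale)."""
    # normalize emission likelihoods per bin to dodge underflow
    log_c = log_b.max(axis=1)
    b = np.exp(log_b - log_c[:, None])
    gamma, xi_sum, scale = _fb_core(
        np.ascontiguousarray(b),
        np.ascontiguousarray(transition),
        np.ascontiguousarray(start),
    )
    loglik = float(np.log(scale).sum() + log_c.sum())
    return gamma, xi_sum, loglik, scale


class BernoulliHMM(BaseEstimator):
    """Hidden Markov model with independent Bernoulli emissions per feature.

    Parameters
    ----------
    n_states : int
        Number of hidden chromatin states K.
    n_iter : int
        Maximum Baum-Welch iterations.
    tol : float
        Stop when the total log-likelihood improves by less than this.
    n_restarts : int
        Independent EM starts (perturbed k-means initializations); the best
        final log-likelihood wins.
    self_transition : float
        Initial self-transition probability (chromatin states are long-lived
        relative to 200-bp bins).
    random_state : int
        Seed controlling initialization; fits are bit-reproducible.

    Attributes
    ----------
    emission_probs_ : (K, F) array of fitted Bernoulli rates.
    transmat_ : (K, K) fitted transition matrix.
    startprob_ : (K,) fitted initial distribution.
    loglik_history_ : per-iteration total log-likelihood of the winning start.
    converged_ : whether the winning start met ``tol`` before ``n_iter``.
    """

    def __init__(
        self,
        n_states: int = 8,
        n_iter: int = 200,
        tol: float = 1e-3,
        n_restarts: int = 3,
        self_transition: float = 0.9,
        random_state: int = 0,
    ):
        self.n_states = n_states
        self.n_iter = n_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.self_transition = self_transition
        self.random_state = random_state

    # -- initialization ----------------------------------------------------

    def _init_params(
        self, X: np.ndarray, rng: np.random.Generator, mode: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        K, F = self.n_states, X.shape[1]
        if K == 1:
            emission = X.mean(axis=0, keepdims=True)
        elif mode == "kmeans":
            sub = X
            if len(X) > 50_000:
                sub = X[rng.choice(len(X), 50_000, replace=False)]
            km = KMeans(
                n_clusters=K,
                n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(sub)
            emission = km.cluster_centers_ + rng.uniform(-0.02, 0.02, size=(K, F))
        elif mode == "patterns":
            # seed states at the K most frequent distinct observed bin
            # patterns — captures composite states k-means tends to blend
            patterns, counts = np.unique(X.astype(np.uint8), axis=0, return_counts=True)
            nonzero = patterns.sum(axis=1) > 0  # every state sees empty bins;
            order = np.argsort(-counts[nonzero])[:K]  # don't waste a state on them
            proto = patterns[nonzero][order].astype(float)
            if len(proto) < K:
                proto = np.vstack([proto, rng.random((K - len(proto), F))])
            emission = 0.8 * proto + 0.1 + rng.uniform(-0.05, 0.05, size=(K, F))
        else:  # random
            emission = rng.uniform(0.05, 0.95, size=(K, F))
        emission = np.clip(emission, EMISSION_CLAMP, 1 - EMISSION_CLAMP)
        if K == 1:
            transition = np.ones((1, 1))
        else:
            off = (1 - self.self_transition) / (K - 1)
            transition = np.full((K, K), off)
            np.fill_diagonal(transition, self.self_transition)
        start = np.full(K, 1 / K)
        return emission, transition, start

    # -- EM ----------------------------------------------------------------

    @staticmethod
    def _log_emission(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
        logE = np.log(emission)
        log1mE = np.log1p(-emission)
        return X @ logE.T + (1 - X) @ log1mE.T

    def _em(
        self,
        sequences: list[np.ndarray],
        emission: np.ndarray,
        transition: np.ndarray,
        start: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
        K = self.n_states
        history: list[float] = []
        converged = False
        # weak MAP smoothing (one pseudo-bin per state at the global feature
        # frequency) keeps surplus states from collapsing to degenerate
        # emission rows when K exceeds the data's effective state count
        marginal = np.vstack([s.mean(axis=0) * len(s) for s in sequences]).sum(
            axis=0
        ) / sum(len(s) for s in sequences)
        pseudo = 1.0
        for _ in range(self.n_iter):
            gamma_sum = np.zeros(K)
            weighted_x = np.zeros((K, sequences[0].shape[1]))
            xi_total = np.zeros((K, K))
            start_acc = np.zeros(K)
            loglik = 0.0
            for X in sequences:
                log_b = self._log_emission(X, emission)
                gamma, xi_sum, ll, _ = _forward_backward(log_b, transition, start)
                loglik += ll
                gamma_sum += gamma.sum(axis=0)
                weighted_x += gamma.T @ X
                xi_total += xi_sum
                start_acc += gamma[0]
            # penalized likelihood is the quantity MAP-EM makes monotone
            log_prior = pseudo * float(
                (marginal[None, :] * np.log(emission)).sum()
                + ((1 - marginal)[None, :] * np.log1p(-emission)).sum()
            )
            history.append(loglik + log_prior)
            if len(history) > 1 and abs(history[-1] - history[-2]) < self.tol:
                converged = True
                break
            emission = np.clip(
                (weighted_x + pseudo * marginal[None, :])
                / (gamma_sum[:, None] + pseudo),
                EMISSION_CLAMP,
                1 - EMISSION_CLAMP,
            )
            if K > 1:
                row = xi_total.sum(axis=1, keepdims=True)
                transition = np.where(row > 0, xi_total / row, 1.0 / K)
                transition /= transition.sum(axis=1, keepdims=True)
            start = start_acc / start_acc.sum()
        return emission, transition, start, history, converged

    def fit(self, X: Sequence[np.ndarray]) -> "BernoulliHMM":
        """Fit by Baum-Welch on a list of (T_i, F) binary sequences."""
        sequences = [np.ascontiguousarray(np.asarray(x, dtype=float)) for x in X]
        if not sequences:
            raise ValueError("no sequences supplied")
        F = sequences[0].shape[1]
        total_bins = sum(len(s) for s in sequences)
        if self.n_states < 1 or self.n_states > total_bins:
            raise ValueError(f"n_states={self.n_states} outside [1, {total_bins}]")
        for s in sequences:
            if s.ndim != 2 or s.shape[1] != F:
                raise ValueError("sequences must share the feature dimension")
        rng = np.random.default_rng(self.random_state)
        stacked = np.vstack(sequences)
        modes = ["patterns", "kmeans"] + ["random"] * max(0, self.n_restarts - 2)
        best = None
        for mode in modes[: max(1, self.n_restarts)]:
            params = self._init_params(stacked, rng, mode)
            em, tr, st, history, conv = self._em(sequences, *params)
            if best is None or history[-1] > best[3][-1]:
                best = (em, tr, st, history, conv)
        self.emission_probs_, self.transmat_, self.startprob_, self.loglik_history_, self.converged_ = best
        self.n_features_in_ = F
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "emission_probs_"):
            raise AttributeError("estimator is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior state probabilities, one row per bin (rows sum to 1)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        log_b = self._log_emission(X, self.emission_probs_)
        gamma, _, _, _ = _forward_backward(log_b, self.transmat_, self.startprob_)
        return gamma

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Posterior-argmax state per bin, labels 1..K."""
        return self.predict_proba(X).argmax(axis=1) + 1

    def score(self, X: np.ndarray) -> float:
        """Total log-likelihood of one sequence under the fitted model."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        log_b = self._log_emission(X, self.emission_probs_)
        _, _, ll, _ = _forward_backward(log_b, self.transmat_, self.startprob_)
        return ll

    def to_emission_model(
        self, feature_names: Sequence[str], bin_size: int = 200
    ) -> EmissionModel:
        self._check_fitted()
        return EmissionModel(
            emission=self.emission_probs_.copy(),
            transition=self.transmat_.copy(),
            start=self.startprob_.copy(),
            feature_names=list(feature_names),
            bin_size=bin_size,
            log_likelihood=float(self.loglik_history_[-1]),
        )


# ---------------------------------------------------------------------------
# module-level pipeline surface


def fit_hmm(
    calls: Sequence[BinaryCalls],
    n_states: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-3,
    n_restarts: int = 3,
) -> EmissionModel:
    """Train the concatenated two-condition chromatin-state model.

    Every (condition, chromosome) pair is an independent sequence; all share
    one parameter set, so states are condition-comparable.
    """
    sequences, feature_names = stack_calls(calls)
    hmm = BernoulliHMM(
        n_states=n_states,
        n_iter=max_iter,
        tol=tol,
        n_restarts=n_restarts,
        random_state=seed,
    )
    hmm.fit([sequences[k] for k in sorted(sequences)])
    return hmm.to_emission_model(feature_names, bin_size=calls[0].bin_size)


def decode_states(model: EmissionModel, calls: Sequence[BinaryCalls]) -> Segmentation:
    """Posterior-decode per-bin states for every condition and chromosome."""
    sequences, feature_names = stack_calls(calls)
    if feature_names != list(model.feature_names):
        raise ValueError(
            f"feature mismatch: model has {model.feature_names}, calls have {feature_names}"
        )
    hmm = BernoulliHMM(n_states=model.n_states)
    hmm.emission_probs_ = np.clip(model.emission, EMISSION_CLAMP, 1 - EMISSION_CLAMP)
    hmm.transmat_ = model.transition
    hmm.startprob_ = model.start
    states = {key: hmm.predict(seq) for key, seq in sequences.items()}
    return Segmentation(states=states, n_states=model.n_states, bin_size=model.bin_size)


def state_enrichment(
    seg: Segmentation,
    query: IntervalSet,
    genome: Genome,
    condition: str | None = None,
) -> dict[int, EnrichmentStat]:
    """Per-state enrichment of a query region set at bin granularity.

    A bin counts as "query" when the query covers >= 1 bp of it. For state k,
    observed = query bins labeled k, expected = (query bins x state-k bins) /
    total bins, with an upper-tail hypergeometric probability.
    """
    bin_size = seg.bin_size
    keys = [k for k in seg.states if condition is None or k[0] == condition]
    if not keys:
        raise ValueError(f"no segmentation for condition {condition!r}")
    query = query if query.flattened else flatten(query)
    if not genome.contains(query):
        raise ValueError("query extends beyond the genome")
    q_by_chrom = query.by_chrom()
    total_bins = 0
    state_bins = np.zeros(seg.n_states, dtype=np.int64)
    query_bins = 0
    obs = np.zeros(seg.n_states, dtype=np.int64)
    for cond, chrom in keys:
        labels = seg.states[(cond, chrom)]
        total_bins += len(labels)
        state_bins += np.bincount(labels - 1, minlength=seg.n_states)
        mask = np.zeros(len(labels), dtype=bool)
        if chrom in q_by_chrom:
            starts, ends = q_by_chrom[chrom]
            for s, e in zip(starts, ends):
                b0 = int(s) // bin_size
                b1 = min(-(-int(e) // bin_size), len(labels))
                mask[b0:b1] = True
        query_bins += int(mask.sum())
        obs += np.bincount(labels[mask] - 1, minlength=seg.n_states)
    out: dict[int, EnrichmentStat] = {}
    for k in range(seg.n_states):
        expected = query_bins * int(state_bins[k]) / total_bins
        fold = obs[k] / expected if expected > 0 else float("nan")
        p = hypergeom_upper_tail(int(obs[k]), query_bins, int(state_bins[k]), total_bins)
        out[k + 1] = EnrichmentStat(
            observed=int(obs[k]), expected=expected, fold=fold, p=p
        )
    return out
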