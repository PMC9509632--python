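"""Binned-signal binarization and two-condition call equalization.

A genome is divided into fixed-width bins (200 bp by default). Each chromatin
feature in each condition contributes a :class:`BinnedTrack` of per-bin
signal. Binarization calls a bin "present" when its count is improbably high
under a local Poisson background; equalization then retains, per feature and
chromosome, only the top-signal n calls in *both* conditions, where n is the
smaller condition's call count. This removes sequencing-depth and IP-efficiency
bias before joint two-condition chromatin-state modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "BinnedTrack",
    "BinaryCalls",
    "PoissonBinarizer",
    "background_subtract",
    "poisson_binarize",
    "equalize_calls",
]


@dataclass
class BinnedTrack:
    """Fixed-width binned non-negative signal, one vector per chromosome."""

    feature: str
    condition: str
    bin_size: int = 200
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, v in self.values.items():
            if v.ndim != 1:
                raise ValueError(f"{chrom}: values must be 1-d")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative signal values")

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def same_shape(self, other: "BinnedTrack | BinaryCalls") -> bool:
        a = {c: len(v) for c, v in self.values.items()}
        other_vecs = other.values if isinstance(other, BinnedTrack) else other.calls
        b = {c: len(v) for c, v in other_vecs.items()}
        return a == b


@dataclass
class BinaryCalls:
    """Per-bin boolean presence calls, same shape as the source track."""

    feature: str
    condition: str
    bin_size: int = 200
    calls: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = {c: np.asarray(v, dtype=bool) for c, v in self.calls.items()}

    def n_calls(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.calls[chrom].sum())
        return int(sum(v.sum() for v in self.calls.values()))


def background_subtract(signal: BinnedTrack, control: BinnedTrack | None) -> BinnedTrack:
    """Subtract a depth-scaled control from the signal, flooring at zero.

    The control is scaled so its total matches the signal's total before
    subtraction. With no control (e.g. accessibility data) the signal passes
    through unchanged.
    """
    if control is None:
        return signal
    if not signal.same_shape(control):
        raise ValueError("signal and control tracks have different shapes")
    ctl_total = control.total()
    scale = signal.total() / ctl_total if ctl_total > 0 else 0.0
    values = {
        chrom: np.maximum(signal.values[chrom] - scale * control.values[chrom], 0.0)
        for chrom in signal.values
    }
    return replace(signal, values=values)


def poisson_binarize(
    track: BinnedTrack,
    control: BinnedTrack | None = None,
    p_threshold: float = 1e-4,
    control_window_bins: int = 25,
) -> BinaryCalls:
    """Call a bin present when its count is improbable under Poisson background.

    The background rate for a bin is the depth-scaled, locally averaged
    control count (a ``control_window_bins`` moving average — the control is
    a low-coverage estimate of a smooth background, so single control reads
    must not dominate the local rate), floored at the genome-wide mean signal
    so zero-coverage control regions cannot produce spurious calls. Without a
    control the rate is the global mean everywhere. A bin is present iff the
    Poisson upper tail ``P(X >= observed | rate)`` is <= ``p_threshold``.
    """
    n_bins = sum(len(v) for v in track.values.values())
    if n_bins == 0:
        raise ValueError("empty track")
    global_mean = track.total() / n_bins
    if control is not None:
        if not track.same_shape(control):
            raise ValueError("signal and control tracks have different shapes")
        ctl_total = control.total()
        scale = track.total() / ctl_total if ctl_total > 0 else 0.0
    calls: dict[str, np.ndarray] = {}
    for chrom, counts in track.values.items():
        if control is not None:
            from scipy.ndimage import uniform_filter1d

            smoothed = uniform_filter1d(
                control.values[chrom],
                size=max(1, control_window_bins),
                mode="nearest",
            )
            rate = np.maximum(scale * smoothed, global_mean)
        else:
            rate = np.full_like(counts, global_mean)
        # upper tail P(X >= k) = sf(k - 1); all-zero background -> no calls
        with np.errstate(divide="ignore"):
            tail = stats.poisson.sf(counts - 1, rate)
        calls[chrom] = (tail <= p_threshold) & (counts > 0) if p_threshold < 1 else np.ones_like(counts, dtype=bool)
    return BinaryCalls(track.feature, track.condition, track.bin_size, calls)


def _top_n_calls(signal: np.ndarray, calls: np.ndarray, n: int) -> np.ndarray:
    """Keep the n called bins with highest signal (ties: earlier bin wins)."""
    idx = np.flatnonzero(calls)
    if len(idx) <= n:
        return calls.copy()
    # stable sort by (-signal, position): mergesort on -signal preserves
    # ascending-position order within ties
    order = np.argsort(-signal[idx], kind="mergesort")
    keep = idx[order[:n]]
    out = np.zeros_like(calls)
    out[keep] = True
    return out


def equalize_calls(
    signal_a: BinnedTrack,
    calls_a: BinaryCalls,
    signal_b: BinnedTrack,
    calls_b: BinaryCalls,
) -> tuple[BinaryCalls, BinaryCalls]:
    """Equalize present-call counts between two conditions, per chromosome.

    For each chromosome, n = min(calls in A, calls in B); each condition
    keeps only its n called bins with the highest (background-subtracted)
    signal, so both conditions end with identical call counts per chromosome.
    """
    if signal_a.feature != signal_b.feature:
        raise ValueError("equalization requires the same feature in both conditions")
    if not (signal_a.same_shape(calls_a) and signal_b.same_shape(calls_b)):
        raise ValueError("signal/calls shape mismatch")
    if {c: len(v) for c, v in signal_a.values.items()} != {
        c: len(v) for c, v in signal_b.values.items()
    }:
        raise ValueError("conditions have different bin layouts")
    out_a: dict[str, np.ndarray] = {}
    out_b: dict[str, np.ndarray] = {}
    for chrom in signal_a.values:
        ca, cb = calls_a.calls[chrom], calls_b.calls[chrom]
        n = min(int(ca.sum()), int(cb.sum()))
        out_a[chrom] = _top_n_calls(signal_a.values[chrom], ca, n)
        out_b[chrom] = _top_n_calls(signal_b.values[chrom], cb, n)
    return (
        BinaryCalls(calls_a.feature, calls_a.condition, calls_a.bin_size, out_a),
        BinaryCalls(calls_b.feature, calls_b.condition, calls_b.bin_size, out_b),
    )


class PoissonBinarizer:
    """Transformer turning binned count tracks into presence calls.

    Parameters
    ----------
    p_threshold : float
        Poisson upper-tail probability at or below which a bin is called
        present (default 1e-4).
    """

    def __init__(self, p_threshold: float = 1e-4):
        self.p_threshold = p_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"p_threshold": self.p_threshold}

    def set_params(self, **params) -> "PoissonBinarizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def transform(
        self, track: BinnedTrack, control: BinnedTrack | None = None
    ) -> BinaryCalls:
        return poisson_binarize(track, control, p_threshold=self.p_threshold)
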