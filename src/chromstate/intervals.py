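"""Genomic interval arithmetic and co-occupancy enrichment statistics.

All coordinates are 0-based, half-open (BED convention). The statistics here
— per-bp fold enrichment with hypergeometric tails, Fisher exact and
chi-squared tests on 2x2 tables, replicate-consistency peak filtering,
p-value-carrying region merging, and enhancer classification — are the
building blocks of every downstream co-occupancy analysis in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "Genome",
    "ContingencyTable2x2",
    "EnrichmentStat",
    "flatten",
    "intersect_bp",
    "fold_enrichment_bp",
    "hypergeom_upper_tail",
    "fisher_exact_2x2",
    "chi_squared_2x2",
    "naive_overlap_peakset",
    "merge_nearby_regions",
    "classify_enhancers",
]

#: Sentinel for an undefined fold (0/0) or odds ratio.
UNDEFINED = float("nan")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Kept sorted by ``(chrom, start, end)``. A *flattened* set additionally
    has no two overlapping or abutting intervals on the same chromosome, so
    its total length equals the number of genomic bp it covers.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), flattened: bool = False):
        self.intervals: list[GenomicInterval] = sorted(intervals)
        if flattened:
            self._check_flat()
        self.flattened = flattened

    def _check_flat(self) -> None:
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if prev.chrom == cur.chrom and cur.start <= prev.end:
                raise ValueError("intervals overlap or abut; set is not flattened")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals, flattened={self.flattened})"

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, in sorted order."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            s, e = out.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]], **kw) -> "IntervalSet":
        return cls((GenomicInterval(c, s, e) for c, s, e in tuples), **kw)


@dataclass
class Genome:
    """Chromosome lengths; ``total_bp`` is the G of per-bp enrichment tests."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains(self, ivset: IntervalSet) -> bool:
        return all(
            iv.chrom in self.chrom_lengths and iv.end <= self.chrom_lengths[iv.chrom]
            for iv in ivset
        )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a, b (first row) and c, d (second row); all >= 0, total > 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentStat:
    """Observed/expected enrichment with its tail probability.

    ``fold`` is NaN when expected is 0 (the undefined sentinel);
    ``odds_ratio`` may be ``inf`` (zero denominator) or NaN (0/0).
    """

    observed: float
    expected: float
    fold: float
    p: float
    odds_ratio: float = UNDEFINED
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# interval arithmetic


def flatten(ivset: IntervalSet) -> IntervalSet:
    """Merge overlapping/abutting intervals into a minimal covering set.

    The covered bp are exactly preserved.
    """
    if ivset.flattened:
        return ivset
    merged: list[GenomicInterval] = []
    for iv in ivset.intervals:  # already sorted
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return IntervalSet(merged, flattened=True)


def _require_flat(*sets: IntervalSet) -> tuple[IntervalSet, ...]:
    return tuple(s if s.flattened else flatten(s) for s in sets)


def intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total bp covered by both flattened sets (two-pointer sweep per chrom)."""
    a, b = _require_flat(a, b)
    a_chroms, b_chroms = a.by_chrom(), b.by_chrom()
    total = 0
    for chrom in set(a_chroms) & set(b_chroms):
        sa, ea = a_chroms[chrom]
        sb, eb = b_chroms[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """The flattened set of bp covered by both A and B."""
    a, b = _require_flat(a, b)
    a_chroms, b_chroms = a.by_chrom(), b.by_chrom()
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_chroms) & set(b_chroms)):
        sa, ea = a_chroms[chrom]
        sb, eb = b_chroms[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                out.append(GenomicInterval(chrom, int(lo), int(hi)))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return IntervalSet(out, flattened=True)


def coverage_bp(query: GenomicInterval, cover: IntervalSet) -> int:
    """bp of ``query`` covered by the flattened set ``cover``."""
    return intersect_bp(IntervalSet([query], flattened=True), cover)


def overlaps_any(query: GenomicInterval, cover: IntervalSet) -> bool:
    """True iff ``query`` shares >= 1 bp with some interval of ``cover``."""
    chroms = cover.by_chrom()
    if query.chrom not in chroms:
        return False
    starts, ends = chroms[query.chrom]
    # first interval with end > query.start
    idx = int(np.searchsorted(ends, query.start, side="right"))
    return idx < len(starts) and starts[idx] < query.end


# ---------------------------------------------------------------------------
# enrichment statistics


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment_bp(a: IntervalSet, b: IntervalSet, genome: Genome) -> EnrichmentStat:
    """Per-genomic-bp [observed / expected] co-occupancy of two interval sets.

    Each genomic bp is one trial: observed is the bp covered by both sets,
    expected is ``|A| * |B| / G``, and the tail probability treats the |B|
    covered bp as successes in a population of G bp from which |A| bp are
    drawn (upper-tail hypergeometric).
    """
    a, b = _require_flat(a, b)
    g = genome.total_bp
    na, nb = a.total_bp(), b.total_bp()
    if na > g or nb > g:
        raise ValueError("interval sets exceed genome size")
    observed = intersect_bp(a, b)
    expected = na * nb / g
    if na == 0 or nb == 0:
        return EnrichmentStat(observed=observed, expected=expected, fold=UNDEFINED, p=1.0)
    fold = observed / expected
    p = hypergeom_upper_tail(observed, na, nb, g)
    return EnrichmentStat(observed=observed, expected=expected, fold=fold, p=p)


def fisher_exact_2x2(table: ContingencyTable2x2) -> EnrichmentStat:
    """Two-tailed Fisher exact test with the sample cross-product odds ratio.

    The two-sided p sums all tables with the observed margins whose point
    probability does not exceed the observed table's. The odds ratio is
    ``a*d / (b*c)`` with an ``inf`` sentinel on a zero denominator and NaN
    when numerator and denominator are both zero (no Haldane correction).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    ad, bc = a * d, b * c
    if bc == 0:
        odds = UNDEFINED if ad == 0 else float("inf")
    else:
        odds = ad / bc
    # p over the margin-fixed family: x successes in first row,
    # x ~ Hypergeom(N=total, K=a+b row margin, n=a+c column margin)
    N = table.total
    K = a + b
    n = a + c
    lo, hi = max(0, n - (N - K)), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    p_obs = stats.hypergeom.pmf(a, N, K, n)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return EnrichmentStat(
        observed=a, expected=K * n / N, fold=a / (K * n / N) if K * n else UNDEFINED,
        p=min(p, 1.0), odds_ratio=odds,
    )


def chi_squared_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table.

    Returns ``(statistic, p)``; a zero margin yields ``(nan, 1.0)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        return UNDEFINED, 1.0
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# peak-set operations


def naive_overlap_peakset(
    pooled: IntervalSet, replicates: Sequence[IntervalSet], min_fraction: float = 0.5
) -> IntervalSet:
    """Replicate-consistency filter for pooled peaks.

    A pooled peak is retained iff, for *every* replicate, at least
    ``min_fraction`` of the peak's length is covered by the union of that
    replicate's peaks (boundary inclusive).
    """
    if not replicates:
        raise ValueError("at least one replicate set is required")
    reps = [r if r.flattened else flatten(r) for r in replicates]
    kept = [
        peak
        for peak in pooled
        if all(coverage_bp(peak, rep) >= min_fraction * len(peak) for rep in reps)
    ]
    return IntervalSet(kept, flattened=pooled.flattened)


def merge_nearby_regions(
    regions: IntervalSet,
    p_values: Sequence[float],
    max_gap: int = 500,
    max_width: int = 5000,
) -> tuple[IntervalSet, np.ndarray, list[list[int]]]:
    """Greedy left-to-right chaining of nearby regions with min-p representation.

    Per chromosome, the current merged region is extended by the next region
    iff the gap is <= ``max_gap`` (inclusive) *and* the resulting width is
    <= ``max_width``. A single input region wider than ``max_width`` passes
    through unmerged. Each merged region carries the minimum p of its members.

    Returns (merged regions, representative p per merged region, member
    indices per merged region).
    """
    if len(p_values) != len(regions):
        raise ValueError("one p-value per region is required")
    merged: list[GenomicInterval] = []
    rep_p: list[float] = []
    members: list[list[int]] = []
    for idx, iv in enumerate(regions):
        p = float(p_values[idx])
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= max_gap
            and iv.start >= merged[-1].start
            and max(iv.end, merged[-1].end) - merged[-1].start <= max_width
        ):
            merged[-1] = GenomicInterval(
                iv.chrom, merged[-1].start, max(iv.end, merged[-1].end)
            )
            rep_p[-1] = min(rep_p[-1], p)
            members[-1].append(idx)
        else:
            merged.append(iv)
            rep_p.append(p)
            members.append([idx])
    return IntervalSet(merged), np.asarray(rep_p), members


# ---------------------------------------------------------------------------
# enhancer classification

PROMOTER_PROXIMAL = "promoter_proximal"
TYPICAL_ENHANCER = "typical_enhancer"
SUPER_ENHANCER_CONSTITUENT = "super_enhancer_constituent"
OTHER = "other"


def _tss_edge_distance(peak: GenomicInterval, positions: np.ndarray) -> int:
    """Nearest distance from the peak's edges to any TSS point (0 if inside)."""
    if positions.size == 0:
        return np.iinfo(np.int64).max
    left = peak.start - positions  # >0 when TSS left of peak
    right = positions - (peak.end - 1)  # >0 when TSS right of peak
    dist = np.maximum(np.maximum(left, right), 0)
    return int(dist.min())


def classify_enhancers(
    h3k27ac: IntervalSet,
    atac: IntervalSet,
    superenhancers: IntervalSet,
    tss: Sequence,
    tss_distance: int = 3000,
) -> list[str]:
    """Classify each H3K27ac peak by regulatory context.

    Classes: ``super_enhancer_constituent`` (accessible peak inside a
    super-enhancer), ``promoter_proximal`` (within +-``tss_distance`` of a
    TSS, boundary inclusive), ``typical_enhancer`` (accessible, strictly
    farther than ``tss_distance`` from every TSS, outside super-enhancers),
    else ``other``. ``tss`` entries need ``chrom`` and ``position`` attributes
    (see :class:`chromstate.geneassoc.TSS`).
    """
    atac, superenhancers = _require_flat(atac, superenhancers)
    tss_by_chrom: dict[str, list[int]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t.position)
    tss_arrays = {c: np.asarray(v, dtype=np.int64) for c, v in tss_by_chrom.items()}
    labels = []
    for peak in h3k27ac:
        is_atac = overlaps_any(peak, atac)
        in_se = overlaps_any(peak, superenhancers)
        d = _tss_edge_distance(peak, tss_arrays.get(peak.chrom, np.empty(0, dtype=np.int64)))
        if is_atac and in_se:
            labels.append(SUPER_ENHANCER_CONSTITUENT)
        elif d <= tss_distance:
            labels.append(PROMOTER_PROXIMAL)
        elif is_atac and not in_se:
            labels.append(TYPICAL_ENHANCER)
        else:
            labels.append(OTHER)
    return labels
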