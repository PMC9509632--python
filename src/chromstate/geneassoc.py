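"""Peak-to-gene assignment and gene-level association statistics.

Peaks are linked to genes through a strand-symmetric promoter-proximal
window (+-3 kb around the TSS by default). Gene sets derived from chromatin
classes are then related to differential-expression tables: hypergeometric
and Fisher set enrichment, chi-squared directional association between two
knockdown experiments, log2 fold-change correlation, and co-regulated gene
intersection across experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    ContingencyTable2x2,
    EnrichmentStat,
    IntervalSet,
    chi_squared_2x2,
    fisher_exact_2x2,
    hypergeom_upper_tail,
)

__all__ = [
    "TSS",
    "DGETable",
    "promoter_proximal_genes",
    "geneset_enrichment",
    "directional_association",
    "fc_correlation",
    "co_regulated_genes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TSS:
    """A transcription start site: a strand-annotated genomic point."""

    gene_id: str
    chrom: str
    position: int  # 0-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.position < 0:
            raise ValueError("TSS position must be non-negative")


@dataclass
class DGETable:
    """Differential-expression results keyed by gene: log2FC and FDR.

    ``detected`` marks genes with transcripts detected in the experiment;
    undetected genes are excluded from cross-experiment comparisons.
    """

    table: pd.DataFrame  # columns: gene_id, log2fc, fdr, detected

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "fdr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DGE table missing columns: {sorted(missing)}")
        if "detected" not in self.table.columns:
            self.table = self.table.assign(detected=True)
        fdr = self.table["fdr"]
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValueError("fdr values outside [0, 1]")
        self.table = self.table.set_index("gene_id", drop=False)

    def detected_genes(self) -> set[str]:
        return set(self.table.loc[self.table["detected"], "gene_id"])

    def significant(self, fdr_cut: float, direction: str | None = None) -> set[str]:
        t = self.table[self.table["detected"] & (self.table["fdr"] < fdr_cut)]
        if direction == "up":
            t = t[t["log2fc"] > 0]
        elif direction == "down":
            t = t[t["log2fc"] < 0]
        return set(t["gene_id"])


def promoter_proximal_genes(
    peaks: IntervalSet, tss: list[TSS], flank: int = 3000
) -> set[str]:
    """Genes with >= 1 peak overlapping the half-open window
    ``[position - flank, position + flank)`` around any of their TSS.

    The window is strand-symmetric. A gene with several (possibly
    conflicting) TSS entries contributes the union of its windows.
    """
    seen: dict[str, set[tuple[str, int]]] = {}
    for t in tss:
        seen.setdefault(t.gene_id, set()).add((t.chrom, t.position))
    for gid, locs in seen.items():
        if len(locs) > 1:
            logger.warning("gene %s has %d distinct TSS; using union of windows", gid, len(locs))
    by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
    for t in tss:
        s, e, g = by_chrom.setdefault(t.chrom, ([], [], []))
        s.append(max(t.position - flank, 0))
        e.append(t.position + flank)
        g.append(t.gene_id)
    out: set[str] = set()
    for chrom, (starts, ends, genes) in by_chrom.items():
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        genes = np.asarray(genes, dtype=object)
        for peak in peaks:
            if peak.chrom != chrom:
                continue
            hit = (starts < peak.end) & (ends > peak.start)
            out.update(genes[hit])
    return out


def geneset_enrichment(
    query: set[str], annotated: set[str], universe: set[str]
) -> EnrichmentStat:
    """Hypergeometric over-representation of ``annotated`` within ``query``.

    Both sets are intersected with the universe; the result carries the
    upper-tail hypergeometric p plus the Fisher odds ratio of the induced
    2x2 membership table.
    """
    if not universe:
        raise ValueError("empty universe")
    query = query & universe
    annotated = annotated & universe
    n_u = len(universe)
    k = len(query & annotated)
    p = hypergeom_upper_tail(k, len(query), len(annotated), n_u)
    a = k
    b = len(query) - k
    c = len(annotated) - k
    d = n_u - a - b - c
    odds = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).odds_ratio if n_u else float("nan")
    expected = len(query) * len(annotated) / n_u
    fold = k / expected if expected > 0 else float("nan")
    return EnrichmentStat(observed=k, expected=expected, fold=fold, p=p, odds_ratio=odds)


def directional_association(
    de_a: DGETable, de_b: DGETable, fdr_cut: float = 0.05
) -> tuple[ContingencyTable2x2 | None, float, float]:
    """Chi-squared test of direction concordance between two experiments.

    Restricted to genes significant (FDR < ``fdr_cut``) in both tables;
    the 2x2 table crosses up/down in A with up/down in B. Returns
    ``(table, statistic, p)``; fewer than 2 shared significant genes, or a
    zero margin, yields ``(table-or-None, nan, 1.0)``.
    """
    sig = de_a.significant(fdr_cut) & de_b.significant(fdr_cut)
    genes = sorted(
        g
        for g in sig
        if de_a.table.loc[g, "log2fc"] != 0 and de_b.table.loc[g, "log2fc"] != 0
    )
    if len(genes) < 2:
        return None, float("nan"), 1.0
    up_a = de_a.table.loc[genes, "log2fc"].to_numpy() > 0
    up_b = de_b.table.loc[genes, "log2fc"].to_numpy() > 0
    a = int(np.sum(up_a & up_b))
    b = int(np.sum(up_a & ~up_b))
    c = int(np.sum(~up_a & up_b))
    d = int(np.sum(~up_a & ~up_b))
    table = ContingencyTable2x2(a, b, c, d)
    stat, p = chi_squared_2x2(table)
    return table, stat, p


def fc_correlation(de_a: DGETable, de_b: DGETable) -> tuple[float, float]:
    """Pearson and Spearman correlation of log2FC over commonly detected genes."""
    shared = sorted(de_a.detected_genes() & de_b.detected_genes())
    if len(shared) < 3:
        raise ValueError("need >= 3 commonly detected genes")
    x = de_a.table.loc[shared, "log2fc"].to_numpy(dtype=float)
    y = de_b.table.loc[shared, "log2fc"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    rs = float(stats.spearmanr(x, y).statistic)
    return r, rs


def co_regulated_genes(
    tables: list[DGETable], fdr_cut: float = 0.05, direction: str = "up"
) -> set[str]:
    """Genes significant with the same direction in every experiment."""
    if not tables:
        return set()
    sets = [t.significant(fdr_cut, direction=direction) for t in tables]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out
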