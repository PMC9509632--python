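"""Readers and writers for the plain-text interchange formats.

BED and bedGraph coordinates are 0-based half-open and round-trip
bit-exactly. Binarized calls use the binarized-track dialect: two header
lines (condition+feature, then chromosome) followed by one 0/1 column per
feature. Fitted models serialize to JSON; segmentations to dense-segment
BED with state labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryCalls, BinnedTrack
from .diffbind import DifferentialResult, RegionCountMatrix
from .geneassoc import TSS, DGETable
from .intervals import Genome, GenomicInterval, IntervalSet
from .screen import FactorCatalog, ScreenResult
from .statemodel import EmissionModel, Segmentation

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "write_binary_calls",
    "read_binary_calls",
    "write_model_json",
    "read_model_json",
    "write_segmentation_bed",
    "read_factor_catalog",
    "read_tss",
    "read_dge_table",
    "read_region_counts",
    "write_differential_results",
    "write_screen_results",
]


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3+ intervals (extra columns ignored)."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            ivs.append(GenomicInterval(chrom, int(start), int(end)))
    return IntervalSet(ivs)


def write_bed(path: str | Path, ivset: IntervalSet, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(ivset):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> Genome:
    """Two-column TSV of chromosome name and length."""
    lengths = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                lengths[chrom] = int(size)
    return Genome(lengths)


def read_bedgraph(
    path: str | Path,
    genome: Genome,
    bin_size: int = 200,
    feature: str = "signal",
    condition: str = "na",
) -> BinnedTrack:
    """Average bedGraph values into fixed-width bins.

    Each bin's value is the coverage-weighted mean of the bedGraph records
    overlapping it (absent bp count as 0).
    """
    sums = {
        c: np.zeros(-(-l // bin_size)) for c, l in genome.chrom_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom not in sums:
                continue
            s, e, v = int(start), int(end), float(value)
            vec = sums[chrom]
            b0, b1 = s // bin_size, -(-e // bin_size)
            for b in range(b0, min(b1, len(vec))):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                vec[b] += v * (hi - lo)
    values = {c: v / bin_size for c, v in sums.items()}
    return BinnedTrack(feature=feature, condition=condition, bin_size=bin_size, values=values)


def write_bedgraph(path: str | Path, track: BinnedTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vec = track.values[chrom]
            for i, v in enumerate(vec):
                if v != 0:
                    fh.write(
                        f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n"
                    )


def write_binary_calls(path: str | Path, calls: Sequence[BinaryCalls]) -> None:
    """Binarized-track dialect: per chromosome, a condition+chrom header pair
    and one 0/1 column per feature."""
    conditions = sorted({c.condition for c in calls})
    if len(conditions) != 1:
        raise ValueError("one file per condition; split the calls first")
    features = [c.feature for c in calls]
    chroms = sorted(calls[0].calls)
    with open(path, "w") as fh:
        for chrom in chroms:
            fh.write(f"{conditions[0]}\t{chrom}\n")
            fh.write("\t".join(features) + "\n")
            cols = np.column_stack([c.calls[chrom].astype(int) for c in calls])
            for row in cols:
                fh.write("\t".join(map(str, row)) + "\n")


def read_binary_calls(path: str | Path, bin_size: int = 200) -> list[BinaryCalls]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    per_feature: dict[str, dict[str, list[int]]] = {}
    condition = None
    while i < len(lines):
        condition, chrom = lines[i].split("\t")
        features = lines[i + 1].split("\t")
        i += 2
        block: list[list[int]] = []
        while i < len(lines) and "\t" in lines[i] and all(
            t in ("0", "1") for t in lines[i].split("\t")
        ):
            block.append([int(t) for t in lines[i].split("\t")])
            i += 1
        mat = np.asarray(block, dtype=bool)
        for j, feat in enumerate(features):
            per_feature.setdefault(feat, {})[chrom] = mat[:, j]
    return [
        BinaryCalls(feature=f, condition=condition, bin_size=bin_size, calls=chroms)
        for f, chroms in per_feature.items()
    ]


def write_model_json(path: str | Path, model: EmissionModel) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_model_json(path: str | Path) -> EmissionModel:
    with open(path) as fh:
        return EmissionModel.from_dict(json.load(fh))


def write_segmentation_bed(path: str | Path, seg: Segmentation) -> None:
    """Dense-segment dialect: runs of a state become one BED record named E<k>,
    with the condition as a trailing column."""
    with open(path, "w") as fh:
        for (cond, chrom) in sorted(seg.states):
            labels = seg.states[(cond, chrom)]
            if labels.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(labels)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(labels)]])
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{s * seg.bin_size}\t{e * seg.bin_size}\tE{labels[s]}\t{cond}\n"
                )


def read_factor_catalog(directory: str | Path) -> FactorCatalog:
    """Directory of BED files; each file stem names a factor."""
    directory = Path(directory)
    factors = {
        p.stem: read_bed(p) for p in sorted(directory.glob("*.bed"))
    }
    if not factors:
        raise ValueError(f"no .bed files under {directory}")
    return FactorCatalog(factors)


def read_tss(path: str | Path) -> list[TSS]:
    """TSS from BED6 (name = gene, start = position) or 4-column TSV
    (gene, chrom, position, strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 6 and parts[1].isdigit() and parts[2].isdigit():
                chrom, start, _end, name, _score, strand = parts[:6]
                out.append(TSS(name, chrom, int(start), strand))
            else:
                gene, chrom, pos, strand = parts[:4]
                out.append(TSS(gene, chrom, int(pos), strand))
    return out


def read_dge_table(path: str | Path) -> DGETable:
    """TSV with columns gene_id, log2fc, fdr (and optional detected)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    rename = {"gene": "gene_id", "log2fc": "log2fc", "logfc": "log2fc", "padj": "fdr"}
    df = df.rename(columns=rename)
    return DGETable(df)


def read_region_counts(bed_path: str | Path, counts_path: str | Path) -> RegionCountMatrix:
    """Regions BED plus a counts TSV whose header row gives condition labels
    (columns ``sample:condition``) and whose first data row gives library sizes."""
    regions = read_bed(bed_path)
    df = pd.read_csv(counts_path, sep="\t")
    conditions = [c.split(":")[1] if ":" in c else c for c in df.columns]
    lib = df.iloc[0].to_numpy(dtype=float)
    counts = df.iloc[1:].to_numpy(dtype=np.int64)
    return RegionCountMatrix(
        regions=regions, counts=counts, sample_condition=conditions, lib_size=lib
    )


def write_region_counts(
    bed_path: str | Path, counts_path: str | Path, m: RegionCountMatrix
) -> None:
    write_bed(bed_path, m.regions)
    cols = [f"s{i + 1}:{c}" for i, c in enumerate(m.sample_condition)]
    with open(counts_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(f"{x:g}" for x in m.lib_size) + "\n")
        for row in m.counts:
            fh.write("\t".join(str(int(x)) for x in row) + "\n")


def write_enrichment_table(
    path: str | Path, stats: dict, label: str = "key"
) -> None:
    """TSV report of named :class:`EnrichmentStat` results."""
    with open(path, "w") as fh:
        fh.write(f"{label}\tobserved\texpected\tfold\tp\todds_ratio\n")
        for key, s in stats.items():
            fh.write(
                f"{key}\t{s.observed:g}\t{s.expected:.6g}\t{s.fold:.6g}\t"
                f"{s.p:.6g}\t{s.odds_ratio:.6g}\n"
            )


def write_differential_results(path: str | Path, results: Iterable[DifferentialResult]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlog2fc\tp\tfdr\tdirection\n")
        for r in results:
            iv = r.merged_region
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.log2fc:.6g}\t{r.p:.6g}\t{r.fdr:.6g}\t{r.direction}\n"
            )


def write_screen_results(path: str | Path, results: Iterable[ScreenResult]) -> None:
    with open(path, "w") as fh:
        fh.write("factor\todds_ratio\tp\toverlap_fraction\tpasses_filters\n")
        for r in sorted(
            results,
            key=lambda r: -np.nan_to_num(r.odds_ratio, nan=-np.inf, posinf=np.inf),
        ):
            fh.write(
                f"{r.factor}\t{r.odds_ratio:.6g}\t{r.p:.6g}\t{r.overlap_fraction:.6g}\t{int(r.passes_filters)}\n"
            )
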