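import numpy as np
import pytest

from chromstate.intervals import Genome, GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000})


def random_interval_set(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    max_len: int = 2_000,
) -> IntervalSet:
    """Random (possibly overlapping) intervals within the genome."""
    chroms = list(genome.chrom_lengths)
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - length))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


def coverage_mask(ivset: IntervalSet, genome: Genome) -> dict[str, np.ndarray]:
    """Per-bp boolean coverage arrays — the brute-force overlap oracle."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome.chrom_lengths.items()}
    for iv in ivset:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
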