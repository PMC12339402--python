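import numpy as np
import pytest

from ladkit.config import Config
from ladkit.core import Genome, GenomicInterval


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def small_genome():
    return Genome({"chr1": 100_000, "chr2": 55_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, genome, labeled=True):
    """Random valid intervals on a genome, unsorted, possibly overlapping."""
    out = []
    chroms = genome.chroms
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        L = genome[chrom]
        start = int(rng.integers(0, L - 1))
        end = int(rng.integers(start + 1, min(L, start + 20_000) + 1))
        out.append(
            GenomicInterval(chrom, start, end, f"iv{i}" if labeled else None)
        )
    return out


def random_disjoint_intervals(rng, genome, p_on=0.3, step=1_000):
    """Sorted non-overlapping intervals tiling random on-runs of a grid."""
    out = []
    for chrom in genome:
        n_steps = genome[chrom] // step
        on = rng.random(n_steps) < p_on
        i = 0
        while i < n_steps:
            if on[i]:
                j = i
                while j < n_steps and on[j]:
                    j += 1
                out.append(GenomicInterval(chrom, i * step, j * step))
                i = j
            else:
                i += 1
    return out
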