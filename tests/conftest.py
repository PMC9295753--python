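import numpy as np
import pytest
from hypothesis import settings

from polyloop.core import GenomicInterval, IntervalSet
from polyloop.synth import SyntheticGenomeSpec

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    return SyntheticGenomeSpec(
        chrom_sizes={"chr1": 20_000_000, "chr2": 15_000_000, "chr3": 10_000_000},
        tad_mean_size=1_000_000,
        bin_size=10_000,
        seed=7,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=5_000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_overlaps(a, b):
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_count_contained(container, intervals):
    return sum(
        1
        for iv in intervals
        if iv.chrom == container.chrom
        and container.start <= iv.start
        and iv.end <= container.end
    )


@pytest.fixture
def interval_set_factory():
    def make(intervals, label="set"):
        return IntervalSet(intervals, label=label)

    return make
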