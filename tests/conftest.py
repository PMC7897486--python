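import numpy as np
import pytest

from serpeak.coverage import Pileup
from serpeak.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=500):
    """Random intervals for overlap/property tests."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def triangular_pileup(summits, heights, half_width, size, total_mapped=10_000_000):
    """Pileup with triangular bumps; the mode of each sits on its summit."""
    depth = np.zeros(size, dtype=np.int64)
    for s, h in zip(summits, heights):
        lo, hi = max(0, s - half_width), min(size, s + half_width + 1)
        x = np.arange(lo, hi)
        tri = (h * np.maximum(0.0, 1.0 - np.abs(x - s) / half_width)).astype(np.int64)
        depth[lo:hi] = np.maximum(depth[lo:hi], tri)
    return Pileup(depth={"chr1": depth}, total_mapped=total_mapped)
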