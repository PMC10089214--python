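import numpy as np
import pytest

from coenhance.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), span=100_000,
                        max_len=500) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


@pytest.fixture
def random_sets_factory(rng):
    def make(n, **kw):
        return random_interval_set(rng, n, **kw)
    return make
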