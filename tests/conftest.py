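import numpy as np
import pytest

from rg4fus.io import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                     max_len=500):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length,
                                   name=f"iv{i}",
                                   score=float(np.round(rng.uniform(), 3))))
    return out
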