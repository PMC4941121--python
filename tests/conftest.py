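import numpy as np
import pytest

from regprior.intervals import GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_peakset(rng, n, label="rand", chroms=("chr1", "chr2"),
                   span=10_000, max_len=400, with_scores=False):
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        score = float(rng.uniform(1, 50)) if with_scores else None
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + length, score))
    return PeakSet(label=label, intervals=ivs)
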