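import itertools

import numpy as np
import pytest

from ofdr import PValueSetCollection

# the grid used for exhaustive comparison against the reference procedures
PGRID = (0.001, 0.01, 0.02, 0.05, 0.2, 0.9)


def small_pvectors(max_len=3):
    """All p-vectors of length 1..max_len over the comparison grid."""
    for n in range(1, max_len + 1):
        for combo in itertools.product(PGRID, repeat=n):
            yield np.array(combo)


@pytest.fixture
def rng():
    return np.random.default_rng(20140414)


def random_collection(rng, m=10, ragged=False, max_q=5):
    """A random (possibly ragged) collection with signed statistics."""
    sizes = rng.integers(1, max_q + 1, size=m) if ragged else np.full(m, max_q)
    p = [rng.uniform(0, 1, n) ** 2 for n in sizes]  # skew small to get rejections
    sign = [rng.choice([-1, 1], n) for n in sizes]
    return PValueSetCollection(p, sign)
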