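import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, max_m=40, max_n=6, max_d=3):
    """A random labeled training set with every class size >= 2."""
    d = int(rng.integers(2, max_d + 1))
    n = int(rng.integers(1, max_n + 1))
    sizes = rng.integers(2, max(3, max_m // d) + 1, size=d)
    m = int(sizes.sum())
    X = rng.normal(scale=rng.uniform(0.5, 3.0), size=(m, n)) + rng.normal(size=n) * 2
    labels = np.concatenate([np.full(s, k + 1) for k, s in enumerate(sizes)])
    perm = rng.permutation(m)
    return X[perm], labels[perm]
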