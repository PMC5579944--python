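import numpy as np
import pytest

from micronmf import CountMatrix, TypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts(rng):
    """8 x 6 Poisson counts around a rank-2 mean."""
    T = np.array([
        [0.30, 0.00], [0.25, 0.05], [0.20, 0.10], [0.15, 0.15],
        [0.05, 0.20], [0.03, 0.20], [0.02, 0.15], [0.00, 0.15],
    ])
    W = rng.uniform(0.2, 1.0, size=(2, 6)) * 500
    X = rng.poisson(T @ W).astype(float)
    X[:, X.sum(axis=0) == 0] = 1
    return CountMatrix(X)


@pytest.fixture
def block_types():
    """Two types with disjoint block supports on 6 features."""
    T = np.zeros((6, 2))
    T[:3, 0] = [0.5, 0.3, 0.2]
    T[3:, 1] = [0.2, 0.3, 0.5]
    return TypeMatrix(T)
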