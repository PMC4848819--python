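import numpy as np
import pytest

from pooldeconv import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """A 30-gene x 12-cell NB-ish matrix with scattered zeros."""
    lam = rng.gamma(2.0, 5.0, size=30)
    theta = rng.uniform(0.5, 2.0, size=12)
    mu = np.outer(lam, theta)
    values = rng.poisson(mu)
    return CountMatrix(values)


@pytest.fixture
def proportional_counts():
    """Zero-free counts exactly proportional across cells: y_ij = lam_i * theta_j."""
    r = np.random.default_rng(7)
    lam = r.integers(1, 60, size=150)
    theta = r.integers(1, 9, size=40)
    return CountMatrix(np.outer(lam, theta)), theta.astype(float)
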