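import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_problem(rng):
    """Small dense problem (m=12, n=10, p=1) drawn from the joint model."""
    m, n = 12, 10
    x = rng.standard_normal((n, 1))
    alpha = rng.standard_normal(m)
    d = rng.standard_normal(n)
    beta = np.zeros((m, 1))
    beta[:4, 0] = rng.normal(2.0, 1.0, size=4)
    sigma2 = np.full(m, 0.05)
    y = (
        alpha[:, None]
        + beta @ x.T
        + d[None, :]
        + rng.standard_normal((m, n)) * np.sqrt(sigma2)[:, None]
    )
    return y, x, sigma2, beta
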