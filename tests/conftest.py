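import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_bb_data():
    """A small overdispersed dataset generated from a beta-binomial
    regression with known coefficients."""
    import fbbreg as f

    g = np.random.default_rng(11)
    x = g.uniform(-1, 1, size=60)
    n = g.poisson(80, size=60) + 1
    mu = 1.0 / (1.0 + np.exp(-(0.5 + 1.5 * x)))
    pi = g.beta(5.0 * mu, 5.0 * (1.0 - mu))
    y = g.binomial(n, pi)
    X = np.column_stack([np.ones_like(x), x])
    return f.RegressionData(y=y, n=n, X=X)
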