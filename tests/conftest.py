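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
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_pair(rng):
    """Well-separated two-class Gaussian data for classifier tests."""
    n = 120
    X0 = rng.normal(0.0, 1.0, (n, 3))
    X1 = rng.normal(0.0, 1.0, (n, 3)) @ np.diag([1.5, 0.7, 1.0]) + [2.0, -1.0, 0.5]
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n)
    return X, y
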