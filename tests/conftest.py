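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
def flat_trace():
    return np.full(2400, 140.0)


@pytest.fixture
def separable_images(rng):
    """Tiny two-class image set: the curve sits in a class-specific row
    band, linearly separable by construction."""
    n = 24
    y = np.array([0, 1] * (n // 2))
    X = np.zeros((n, 30, 300))
    for i in range(n):
        row = (5 if y[i] == 1 else 20) + int(rng.integers(-3, 4))
        X[i, row, :] = 1.0
    return X, y
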