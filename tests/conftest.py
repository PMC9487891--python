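import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_pli_matrix(rng, n, low=0.05, high=0.95):
    """Symmetric zero-diagonal matrix with continuous (tie-free) weights."""
    m = rng.uniform(low, high, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
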