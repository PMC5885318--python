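import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import binom

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20180404)


def exact_binomial_ci(n: int, p: float, confidence: float = 0.99) -> tuple[int, int]:
    """Central exact-binomial acceptance region for the rejection count."""
    lo, hi = binom.interval(confidence, n, p)
    return int(lo), int(hi)
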