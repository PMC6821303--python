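import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "pria",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pria")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def noisy_trace(rng):
    """A realistic-looking 30-cycle trace: lag, linear rise, mild noise."""
    from pria import TraceSimConfig, simulate_trace

    return simulate_trace(TraceSimConfig(seed=11), label="demo")
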