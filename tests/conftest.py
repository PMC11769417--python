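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
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_trace_500hz():
    """Five noise-free half-sine pulses (A=80 m/s², T=0.1 s) at 500 Hz."""
    from strikevel import StrikeSimConfig, simulate_trace

    cfg = StrikeSimConfig(sampling_rate=500.0, noise_sd=0.0, seed=1)
    return simulate_trace(cfg)
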