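import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actithigh.signal_io import Recording

# One derandomised profile for the whole suite: property tests explore the
# same example sets on every run, so failures are reproducible.
settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_recording():
    """60 s of quiet standing-like signal at 100 Hz."""
    n = 6000
    t = np.arange(n) / 100.0
    rng = np.random.default_rng(0)
    a = np.tile([1.0, 0.0, 0.0], (n, 1)) + rng.normal(0, 0.01, (n, 3))
    return Recording(t=t, a=a, fs=100.0)
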