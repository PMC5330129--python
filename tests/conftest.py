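import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qrsgram import Signal, SynthConfig, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_fixture():
    """A 30 s clean 75 bpm synthetic record with ground truth."""
    return generate(SynthConfig(duration_s=30.0, mean_rr_s=0.8, seed=1))


@pytest.fixture(scope="session")
def long_jittered_fixture():
    """A 5-minute record with 50 ms RR jitter."""
    return generate(SynthConfig(duration_s=300.0, mean_rr_s=0.8, rr_jitter_s=0.05, seed=3))


@pytest.fixture()
def sine_signal():
    def make(freq_hz: float, fs: float = 360.0, duration_s: float = 10.0) -> Signal:
        t = np.arange(int(duration_s * fs)) / fs
        return Signal(samples=np.sin(2 * np.pi * freq_hz * t), fs=fs)

    return make
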