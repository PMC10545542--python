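import numpy as np
import pytest

from swimencode.kinematics import TailTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sine_trace(
    amp_deg: float = 15.0,
    freq_hz: float = 20.0,
    duration_s: float = 0.25,
    rate_hz: float = 300.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TailTrace:
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    angle = amp_deg * np.sin(2 * np.pi * freq_hz * t)
    if noise_sigma > 0:
        angle = angle + np.random.default_rng(seed).normal(0, noise_sigma, t.size)
    return TailTrace(time_s=t, angle_deg=angle, rate_hz=rate_hz)


@pytest.fixture
def sine_trace():
    return make_sine_trace()
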