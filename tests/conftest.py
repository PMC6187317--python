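import numpy as np
import pytest

from plugcyte.model_core import AcquisitionSpec, CalibrationCurve, ChannelGeometry
from plugcyte.synthetic_data import Trace


@pytest.fixture
def geometry():
    return ChannelGeometry()


@pytest.fixture
def calibration():
    return CalibrationCurve(gain_k=85.0)


def build_trapezoid_trace(
    pulses,
    duration_ms=100.0,
    baseline=10.0,
    noise_sd=0.0,
    sampling_rate=100.0,
    seed=0,
    saturation=None,
):
    """Construct a trace from explicit (t0_ms, t_rise, t_stable, t_decline,
    height) tuples — an oracle independent of the simulator's cell model."""
    n = int(round(duration_ms * sampling_rate))
    t_ms = np.arange(n) / sampling_rate
    y = np.full(n, float(baseline))
    for t0, tr, ts, td, h in pulses:
        knots = np.array([t0, t0 + tr, t0 + tr + ts, t0 + tr + ts + td])
        y += np.interp(t_ms, knots, [0.0, h, h, 0.0], left=0.0, right=0.0)
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    if saturation is not None:
        y = np.minimum(y, saturation)
    return Trace(t_ms / 1000.0, y, sampling_rate)


@pytest.fixture
def make_trace():
    return build_trapezoid_trace
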