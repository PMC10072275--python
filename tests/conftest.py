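import numpy as np
import pytest

from nmjcal.datatypes import StimWindow, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def power_law_trace():
    """Noiseless pure power-law bleach trace (a=1000, b=-0.05, 100 frames)."""
    n = 100
    values = 1000.0 * np.power(np.arange(n) + 1.0, -0.05)
    return Trace(values, 50.0, StimWindow(1.5, 0.2, 40.0))


def make_dff_trace(values, frame_rate_hz=50.0):
    return Trace(np.asarray(values, dtype=float), frame_rate_hz)
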