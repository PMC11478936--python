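import numpy as np
import pytest

from isofame.background import BackgroundEstimate
from isofame.trace_io import IsotopeTrace


def gaussian(t: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-(((t - mu) / sigma) ** 2) / 2)


def make_trace(t, i2, ratio: float = 3.0e-4, meta=None) -> IsotopeTrace:
    """Trace whose mass-3 channel is a fixed multiple of mass-2."""
    i2 = np.asarray(i2, dtype=float)
    return IsotopeTrace(np.asarray(t, float), i2, ratio * i2, meta or {})


def flat_background(n: int, b2: float = 0.0, b3: float = 0.0) -> BackgroundEstimate:
    return BackgroundEstimate("dynamic", np.full(n, float(b2)), np.full(n, float(b3)))


@pytest.fixture
def time_axis():
    return np.arange(0.0, 600.0, 0.25)
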