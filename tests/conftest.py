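import numpy as np
import pytest

from striakit.photometry import ProcessedTrace
from striakit.simulate import transient_kernel


def make_trace(z: np.ndarray, rate_hz: float = 120.0) -> ProcessedTrace:
    """Wrap a bare z array as a ProcessedTrace for detector-level tests."""
    z = np.asarray(z, dtype=float)
    return ProcessedTrace(time_s=np.arange(len(z)) / rate_hz, z=z,
                          rate_hz=rate_hz)


def inject_kernels(z: np.ndarray, rate_hz: float, times_s, amp: float,
                   rise_s: float = 0.3, decay_s: float = 1.5) -> np.ndarray:
    """Add peak-normalized transient kernels of height ``amp`` at the given
    onset times; returns a copy."""
    out = z.copy()
    kernel = amp * transient_kernel(rise_s, decay_s, rate_hz)
    for t in times_s:
        i = int(round(t * rate_hz))
        seg = kernel[: len(out) - i]
        out[i:i + len(seg)] += seg
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240707)
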