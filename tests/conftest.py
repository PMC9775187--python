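import numpy as np
import pytest

from aepannot import Waveform, apply_display_filters, build_time_axis
from aepannot.synth import N_SAMPLES, SAMPLE_RATE_HZ


def gaussian_trace(subtype: str, comps) -> np.ndarray:
    """Sum of (latency_ms, amplitude_uv, sigma_ms) Gaussians on the standard axis."""
    t = build_time_axis(N_SAMPLES, SAMPLE_RATE_HZ[subtype])
    y = np.zeros_like(t)
    for mu, a, s in comps:
        y += a * np.exp(-((t - mu) ** 2) / (2 * s**2))
    return y


@pytest.fixture
def make_waveform():
    """Build a waveform from Gaussian components, optionally display-filtered.

    ``filtered="flag"`` marks the raw trace as filtered without running the
    filters — handy for exercising selection logic on exactly-known
    amplitudes.
    """

    def _make(subtype, comps, filtered=True):
        y = gaussian_trace(subtype, comps)
        w = Waveform(
            subtype=subtype,
            amplitudes=y,
            sample_rate=SAMPLE_RATE_HZ[subtype],
            filtered=False,
        )
        if filtered == "flag":
            w.filtered = True
            return w
        if filtered:
            return apply_display_filters(w)
        return w

    return _make
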