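"""Candidate peak/trough detection with a fluctuation-suppressing window.

Evoked-potential traces carry small residual-noise wiggles even after
averaging and display filtering; annotators must therefore consider only
extrema that dominate a neighbourhood, not every sign change of the first
difference.  A sample is a *peak* here if it is the maximum of a ±m-sample
window (truncated at the boundaries) and strictly exceeds at least one
immediate neighbour; exact-tie plateaus report their earliest sample.
Troughs are peaks of the negated signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .preprocess import Waveform

__all__ = ["ExtremaSet", "find_local_extrema"]

DEFAULT_WINDOW = 4  # samples; per-subtype override lives in the rule config


@dataclass(frozen=True)
class ExtremaSet:
    """Strictly increasing candidate peak and trough indices (disjoint)."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    window_m: int

    def of_polarity(self, polarity: str) -> np.ndarray:
        if polarity == "peak":
            return self.peak_indices
        if polarity == "trough":
            return self.trough_indices
        raise ValueError(f"unknown polarity {polarity!r}")


def _windowed_peaks(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size
    # max over [i-m, i+m] with truncated boundary windows
    wmax = maximum_filter1d(x, size=2 * m + 1, mode="constant", cval=-np.inf)
    is_max = x >= wmax
    left = np.empty(n, dtype=bool)
    right = np.empty(n, dtype=bool)
    left[0] = False
    left[1:] = x[:-1] < x[1:]  # strictly above left neighbour
    right[-1] = False
    right[:-1] = x[1:] < x[:-1]  # strictly above right neighbour
    plateau_cont = np.zeros(n, dtype=bool)
    plateau_cont[1:] = x[:-1] == x[1:]  # not the earliest sample of a plateau
    return np.nonzero(is_max & (left | right) & ~plateau_cont)[0]


def find_local_extrema(w: Waveform | np.ndarray, m: int = DEFAULT_WINDOW) -> ExtremaSet:
    """All ±m-window maxima (peaks) and minima (troughs) of the signal.

    Accepts a :class:`~aepannot.preprocess.Waveform` or a bare array.
    Boundary samples are eligible, with truncated windows.  ``m`` must be
    at least 1 and less than half the signal length.
    """
    x = w.amplitudes if isinstance(w, Waveform) else np.asarray(w, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if m < 1:
        raise ValueError("window m must be >= 1")
    if x.size <= 2 * m:
        raise ValueError(
            f"window m={m} too large for a signal of {x.size} samples"
        )
    peaks = _windowed_peaks(x, m)
    troughs = _windowed_peaks(-x, m)
    return ExtremaSet(peak_indices=peaks, trough_indices=troughs, window_m=m)
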