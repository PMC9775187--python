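"""Post-auricular-muscle (PAM) artifact screening for AMLR recordings.

The PAM reflex contaminates AMLR traces as a sharp spike at roughly
13–15 ms — before the basal Pa component — with an amplitude much larger
than Pa's.  Such recordings are clinically unusable and should be excluded
before scoring an annotator.  The operational criterion here: an extremum
inside the PAM window whose absolute amplitude reaches ``pam_ratio`` times
the reference amplitude (Pa's when annotated; otherwise the largest
absolute amplitude inside the Pa core interval; if even that is zero, the
waveform RMS) flags the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import Annotation, RuleConfig, default_amlr_rules
from .eclipse_io import AMLR
from .extrema import ExtremaSet
from .preprocess import Waveform

__all__ = ["PamResult", "detect_pam", "DEFAULT_PAM_WINDOW_MS", "DEFAULT_PAM_RATIO"]

DEFAULT_PAM_WINDOW_MS = (13.0, 15.0)
DEFAULT_PAM_RATIO = 2.0


@dataclass(frozen=True)
class PamResult:
    """Outcome of the PAM screen; spike fields are set only when detected."""

    detected: bool
    spike_latency_ms: float | None = None
    spike_amplitude_uv: float | None = None
    ratio_to_pa: float | None = None


def detect_pam(
    w: Waveform,
    ex: ExtremaSet,
    ann: Annotation,
    pam_window_ms: tuple[float, float] = DEFAULT_PAM_WINDOW_MS,
    pam_ratio: float = DEFAULT_PAM_RATIO,
    cfg: RuleConfig | None = None,
) -> PamResult:
    """Screen one filtered AMLR waveform for a PAM spike.

    *ann* must be the annotation computed from *w* (Pa may be NA).  When
    several extrema in the window exceed the threshold, the largest in
    absolute amplitude is reported as the spike.
    """
    if w.subtype != AMLR:
        raise ValueError("PAM screening applies to AMLR waveforms only")
    if pam_ratio <= 0:
        raise ValueError("pam_ratio must be positive")
    if cfg is None:
        cfg = default_amlr_rules()

    t = w.times_ms
    amps = w.amplitudes

    pa = ann.waves.get("Pa")
    if pa is not None:
        reference = abs(pa.amplitude_uv)
    else:
        lo, hi = cfg.interval_rules["Pa"].core_ms
        in_core = (t >= lo) & (t <= hi)
        reference = float(np.max(np.abs(amps[in_core]))) if in_core.any() else 0.0
    if reference == 0.0:
        reference = float(np.sqrt(np.mean(amps**2)))
    if reference == 0.0:
        return PamResult(detected=False)

    wlo, whi = pam_window_ms
    candidates = [
        int(i)
        for i in np.concatenate([ex.peak_indices, ex.trough_indices])
        if wlo <= t[i] <= whi and abs(amps[i]) >= pam_ratio * reference
    ]
    if not candidates:
        return PamResult(detected=False)
    spike = max(candidates, key=lambda i: abs(amps[i]))
    return PamResult(
        detected=True,
        spike_latency_ms=float(t[spike]),
        spike_amplitude_uv=float(amps[spike]),
        ratio_to_pa=float(abs(amps[spike]) / reference),
    )
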