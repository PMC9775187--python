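"""Synthetic ABR/AMLR recordings with known ground-truth wave positions.

Clinical evoked-potential data is not redistributable, so every stage of
the pipeline is exercised on generated recordings instead: a clean template
built as a sum of Gaussian-shaped components (positive for peaks, negative
for troughs) on the standard 450-sample axis, with independent Gaussian
noise added to each of the two sweep buffers, and an optional large PAM
spike for AMLR.  Ground truth is the extremum of the clean template nearest
each component — so latency shifts caused by overlapping neighbours are
reflected in the gold standard, exactly as a clinician marking the trace
would see them.

Benchmark sets draw component latencies uniformly inside the annotation
rule tables' core intervals, subject to the same inter-wave gap rules the
annotator enforces, emulating a normative population.  See
``docs/methods.md`` for the default amplitudes, widths and noise levels and
what they do (and do not) emulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import RuleConfig, default_rules
from .eclipse_io import (
    ABR,
    AMLR,
    WAVE_LABELS,
    RawRecording,
    write_recording_xml,
)
from .preprocess import build_time_axis

__all__ = [
    "N_SAMPLES",
    "SAMPLE_RATE_HZ",
    "Component",
    "SynthParams",
    "BenchmarkSpec",
    "GenerationError",
    "default_benchmark_spec",
    "component_extrema",
    "generate_recording",
    "generate_benchmark",
]

N_SAMPLES = 450
SAMPLE_RATE_HZ = {ABR: 30000.0, AMLR: 3000.0}
_WINDOW_MS = {ABR: 15.0, AMLR: 150.0}

_MAX_REJECTION_TRIES = 1000


class GenerationError(ValueError):
    """Invalid generation parameters or infeasible constraint combination."""


@dataclass(frozen=True)
class Component:
    """One Gaussian wave component (negative amplitude for a trough)."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float  # Gaussian sigma


@dataclass
class SynthParams:
    """Full description of one synthetic recording."""

    subtype: str
    components: dict[str, Component]
    buffer_noise_sd_uv: float = 0.0
    pam_spike: Component | None = None
    seed: int = 0
    raw_to_microvolt: float = 0.01
    patient_id: str = "synthetic"
    ear: str = "unknown"
    stimulus_intensity: float | None = 80.0

    def validate(self) -> None:
        if self.subtype not in SAMPLE_RATE_HZ:
            raise GenerationError(f"unknown subtype {self.subtype!r}")
        window = _WINDOW_MS[self.subtype]
        for label, comp in self.components.items():
            if not 0 <= comp.latency_ms <= window:
                raise GenerationError(
                    f"{label}: latency {comp.latency_ms} ms outside the "
                    f"{window} ms analysis window"
                )
            if comp.width_ms <= 0:
                raise GenerationError(f"{label}: width must be positive")
        if self.buffer_noise_sd_uv < 0:
            raise GenerationError("noise sd must be >= 0")
        if self.pam_spike is not None and self.subtype != AMLR:
            raise GenerationError("PAM spikes apply to AMLR only")


@dataclass
class BenchmarkSpec:
    """Population-level randomisation settings for benchmark sets.

    ``latency_ranges_ms`` defaults to the annotation rules' core intervals;
    draws are rejected until every configured inter-wave gap rule holds and
    consecutive components are at least ``min_separation_ms`` apart.
    """

    amplitude_ranges_uv: dict[str, tuple[float, float]]
    width_ms: float
    buffer_noise_sd_uv: float
    min_separation_ms: float = 0.0
    latency_ranges_ms: dict[str, tuple[float, float]] | None = None
    pam_amplitude_factor: tuple[float, float] = (3.0, 6.0)
    pam_width_ms: float = 2.0
    pam_latency_range_ms: tuple[float, float] = (13.5, 14.5)


_DEFAULT_SPECS = {
    # ABR: sub-microvolt peaks, sharp (sigma 0.25 ms); V the largest.
    ABR: BenchmarkSpec(
        amplitude_ranges_uv={
            "I": (0.2, 0.4),
            "II": (0.2, 0.4),
            "III": (0.2, 0.4),
            "IV": (0.2, 0.4),
            "V": (0.4, 0.5),
        },
        width_ms=0.25,
        buffer_noise_sd_uv=0.05,
        min_separation_ms=0.8,
    ),
    # AMLR: broad (sigma 3 ms) components; Pa the largest.
    AMLR: BenchmarkSpec(
        amplitude_ranges_uv={
            "Na": (-1.0, -0.5),
            "Pa": (1.0, 1.5),
            "Nb": (-1.0, -0.5),
            "Pb": (0.5, 1.0),
        },
        width_ms=3.0,
        buffer_noise_sd_uv=0.1,
        min_separation_ms=0.0,
    ),
}


def default_benchmark_spec(subtype: str) -> BenchmarkSpec:
    spec = _DEFAULT_SPECS[subtype]
    return replace(spec, amplitude_ranges_uv=dict(spec.amplitude_ranges_uv))


def _template(p: SynthParams, t_ms: np.ndarray) -> np.ndarray:
    y = np.zeros_like(t_ms)
    comps = list(p.components.values())
    if p.pam_spike is not None:
        comps.append(p.pam_spike)
    for c in comps:
        y += c.amplitude_uv * np.exp(-((t_ms - c.latency_ms) ** 2) / (2 * c.width_ms**2))
    return y


def _gold_from_template(
    p: SynthParams, t_ms: np.ndarray, template: np.ndarray
) -> dict[str, int]:
    """Per-component extremum of the clean template.

    Each component is searched within ±1.5 sigma of its nominal latency,
    shrunk to half the distance to the nearest *same-polarity* component so
    a larger neighbour cannot capture the search (an opposite-polarity
    neighbour cannot: a trough never wins an argmax).  A gold sample that
    is not a local extremum of matching polarity signals merged components
    and raises a warning (the merged extremum is kept as gold).
    """
    gold: dict[str, int] = {}
    entries = [(lb, c.latency_ms, c.amplitude_uv) for lb, c in p.components.items()]
    if p.pam_spike is not None:
        entries.append(("__pam__", p.pam_spike.latency_ms, p.pam_spike.amplitude_uv))
    for label, comp in p.components.items():
        same_polarity = [
            lat for lb, lat, amp in entries
            if lb != label and (amp >= 0) == (comp.amplitude_uv >= 0)
        ]
        radius = 1.5 * comp.width_ms
        if same_polarity:
            nearest = min(abs(comp.latency_ms - v) for v in same_polarity)
            radius = min(radius, nearest / 2.0)
        mask = np.abs(t_ms - comp.latency_ms) <= radius
        if not mask.any():
            mask = np.argmin(np.abs(t_ms - comp.latency_ms))
            mask = np.arange(len(t_ms)) == mask
        idx = np.nonzero(mask)[0]
        seg = template[idx]
        pick = idx[np.argmax(seg) if comp.amplitude_uv >= 0 else np.argmin(seg)]
        lo, hi = max(pick - 1, 0), min(pick + 1, len(t_ms) - 1)
        is_extremum = (
            (template[pick] >= template[lo] and template[pick] >= template[hi])
            if comp.amplitude_uv >= 0
            else (template[pick] <= template[lo] and template[pick] <= template[hi])
        )
        if not is_extremum:
            warnings.warn(
                f"{label}: overlapping components merged near "
                f"{comp.latency_ms:.2f} ms; gold taken from the merged extremum",
                stacklevel=2,
            )
        gold[label] = int(pick)
    return gold


def component_extrema(
    p: SynthParams, filter_spec=None
) -> dict[str, int]:
    """Noise-free component extrema, optionally on the display-filtered trace.

    With ``filter_spec=None`` this is exactly ``gold_waves`` (clean-template
    extrema).  Passing a :class:`~aepannot.preprocess.DisplayFilterSpec`
    (or ``"default"``) first runs the template through the display filters
    and maps each component to the nearest local extremum of matching
    polarity on the filtered trace — the positions an ideal annotator of
    the filtered trace would mark, which is the right oracle for testing
    selection logic in isolation from filter-induced latency displacement.
    """
    from .extrema import find_local_extrema
    from .preprocess import Waveform, apply_display_filters, default_display_filter

    p.validate()
    rate = SAMPLE_RATE_HZ[p.subtype]
    t_ms = build_time_axis(N_SAMPLES, rate)
    template = _template(p, t_ms)
    if filter_spec is None:
        return _gold_from_template(p, t_ms, template)
    if filter_spec == "default":
        filter_spec = default_display_filter(p.subtype)
    w = Waveform(subtype=p.subtype, amplitudes=template, sample_rate=rate)
    filtered = apply_display_filters(w, filter_spec).amplitudes
    ex = find_local_extrema(filtered)
    out: dict[str, int] = {}
    for label, comp in p.components.items():
        pool = ex.peak_indices if comp.amplitude_uv >= 0 else ex.trough_indices
        if len(pool) == 0:
            continue
        out[label] = int(min(pool, key=lambda i: abs(t_ms[i] - comp.latency_ms)))
    return out


def generate_recording(p: SynthParams) -> RawRecording:
    """Render one recording: clean template plus independent buffer noise.

    ``gold_waves`` holds the clean-template extremum of each component.
    Both buffers receive independent noise draws from the seeded generator,
    so averaging them halves the noise variance, as with interleaved sweep
    sub-averages on the device.
    """
    p.validate()
    rate = SAMPLE_RATE_HZ[p.subtype]
    t_ms = build_time_axis(N_SAMPLES, rate)
    template = _template(p, t_ms)
    gold = _gold_from_template(p, t_ms, template)

    rng = np.random.default_rng(p.seed)
    noise_a = rng.normal(0.0, p.buffer_noise_sd_uv, N_SAMPLES)
    noise_b = rng.normal(0.0, p.buffer_noise_sd_uv, N_SAMPLES)
    scale = p.raw_to_microvolt
    rec = RawRecording(
        subtype=p.subtype,
        buffer_a=(template + noise_a) / scale,
        buffer_b=(template + noise_b) / scale,
        sample_rate=rate,
        prestimulus_samples=0,
        raw_to_microvolt=scale,
        stimulus_intensity=p.stimulus_intensity,
        ear=p.ear,
        patient_id=p.patient_id,
        gold_waves=gold,
    )
    rec.validate()
    return rec


def _draw_latencies(
    subtype: str,
    rules: RuleConfig,
    spec: BenchmarkSpec,
    rng: np.random.Generator,
) -> dict[str, float]:
    labels = WAVE_LABELS[subtype]
    ranges = spec.latency_ranges_ms or {
        lb: rules.interval_rules[lb].core_ms for lb in labels
    }
    for _ in range(_MAX_REJECTION_TRIES):
        lat = {lb: rng.uniform(*ranges[lb]) for lb in labels}
        ordered = [lat[lb] for lb in labels]
        if any(b - a < spec.min_separation_ms or b <= a
               for a, b in zip(ordered, ordered[1:])):
            continue
        ok = True
        for grule in rules.inter_wave_rules:
            if grule.from_label in lat and grule.to_label in lat:
                gap = lat[grule.to_label] - lat[grule.from_label]
                glo, ghi = grule.allowed_gap_ms
                if not glo <= gap <= ghi:
                    ok = False
                    break
        if ok:
            return lat
    raise GenerationError(
        f"could not satisfy the {subtype} latency constraints after "
        f"{_MAX_REJECTION_TRIES} tries"
    )


def generate_benchmark(
    n: int,
    subtype: str,
    seed: int,
    *,
    rules: RuleConfig | None = None,
    spec: BenchmarkSpec | None = None,
    pam_fraction: float = 0.0,
    out_dir: str | Path | None = None,
    return_params: bool = False,
):
    """Generate *n* recordings with per-recording randomised components.

    Latencies are uniform inside the rule tables' core intervals subject to
    the inter-wave gap rules; amplitudes uniform in the spec's per-wave
    ranges (Pa/V the largest by construction); widths fixed.  A fraction
    ``pam_fraction`` of AMLR recordings receives an injected PAM spike,
    marked in the gold table's ``has_pam`` column.  With *out_dir*, one XML
    file per recording plus ``gold.csv`` are written.

    Returns the recordings and a tidy gold table (one row per wave, with
    sample index, latency, amplitude and the PAM flag); with
    ``return_params`` the per-recording :class:`SynthParams` come third.
    """
    if n < 1:
        raise GenerationError("n must be >= 1")
    if not 0.0 <= pam_fraction <= 1.0:
        raise GenerationError("pam_fraction must lie in [0, 1]")
    if pam_fraction > 0 and subtype != AMLR:
        raise GenerationError("PAM spikes apply to AMLR only")
    if rules is None:
        rules = default_rules(subtype)
    if spec is None:
        spec = default_benchmark_spec(subtype)

    rng = np.random.default_rng(seed)
    n_pam = int(round(pam_fraction * n))
    pam_ids = set(rng.choice(n, size=n_pam, replace=False)) if n_pam else set()

    recordings: list[RawRecording] = []
    all_params: list[SynthParams] = []
    rows: list[dict] = []
    t_ms = build_time_axis(N_SAMPLES, SAMPLE_RATE_HZ[subtype])
    for i in range(n):
        rec_id = f"{subtype.lower()}_{i:04d}"
        lat = _draw_latencies(subtype, rules, spec, rng)
        comps = {
            lb: Component(
                latency_ms=lat[lb],
                amplitude_uv=rng.uniform(*spec.amplitude_ranges_uv[lb]),
                width_ms=spec.width_ms,
            )
            for lb in WAVE_LABELS[subtype]
        }
        pam = None
        if i in pam_ids:
            factor = rng.uniform(*spec.pam_amplitude_factor)
            pam = Component(
                latency_ms=rng.uniform(*spec.pam_latency_range_ms),
                amplitude_uv=factor * abs(comps["Pa"].amplitude_uv),
                width_ms=spec.pam_width_ms,
            )
        params = SynthParams(
            subtype=subtype,
            components=comps,
            buffer_noise_sd_uv=spec.buffer_noise_sd_uv,
            pam_spike=pam,
            seed=int(rng.integers(0, 2**31)),
            patient_id=rec_id,
            ear="left" if i % 2 == 0 else "right",
            stimulus_intensity=80.0,
        )
        rec = generate_recording(params)
        recordings.append(rec)
        all_params.append(params)
        for lb, idx in rec.gold_waves.items():
            rows.append(
                {
                    "recording": rec_id,
                    "wave": lb,
                    "gold_index": idx,
                    "latency_ms": float(t_ms[idx]),
                    "amplitude_uv": comps[lb].amplitude_uv,
                    "has_pam": i in pam_ids,
                }
            )
    gold = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_recording_xml(rec, out_dir / f"{rec.patient_id}.xml")
        gold.to_csv(out_dir / "gold.csv", index=False)
    if return_params:
        return recordings, gold, all_params
    return recordings, gold
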