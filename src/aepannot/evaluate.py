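"""Scoring predicted annotations against a gold standard.

A predicted wave position is accepted as correct when it deviates from the
gold (clinician or generator) position by at most a fixed number of samples
— ±4 by default, which at the standard 450-sample geometry corresponds to
4·15/450 ≈ 0.13 ms for ABR and 4·150/450 ≈ 1.33 ms for AMLR.  Waves absent
from the gold standard are excluded from the denominator; a gold wave the
predictor missed counts as unmatched (both behaviours are flags).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import Annotation
from .eclipse_io import ABR, WAVE_LABELS

__all__ = [
    "N_SAMPLES_STANDARD",
    "WINDOW_MS",
    "WaveScore",
    "MatchReport",
    "sample_deviation_to_ms",
    "compute_match_rates",
    "deviation_table",
]

N_SAMPLES_STANDARD = 450
#: Analysis-window duration per subtype at the standard geometry.
WINDOW_MS = {"ABR": 15.0, "AMLR": 150.0}

GoldMap = "dict[str, int] | Annotation | None"


@dataclass(frozen=True)
class WaveScore:
    n_evaluable: int
    n_matched: int

    @property
    def match_rate(self) -> float | None:
        """Percentage matched, or ``None`` when nothing was evaluable."""
        if self.n_evaluable == 0:
            return None
        return 100.0 * self.n_matched / self.n_evaluable


@dataclass
class MatchReport:
    """Per-wave match statistics at a fixed sample tolerance."""

    subtype: str
    tolerance_samples: int
    per_wave: dict[str, WaveScore]

    @property
    def tolerance_ms(self) -> float:
        return sample_deviation_to_ms(self.tolerance_samples, self.subtype)

    def match_rate(self, label: str) -> float | None:
        return self.per_wave[label].match_rate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "wave": label,
                "n_evaluable": s.n_evaluable,
                "n_matched": s.n_matched,
                "match_rate_pct": s.match_rate,
            }
            for label, s in self.per_wave.items()
        ]
        return pd.DataFrame(rows)


def sample_deviation_to_ms(k: int, subtype: str) -> float:
    """Convert a deviation of *k* samples to milliseconds.

    Both subtypes use 450-sample epochs, so ``k * window_ms / 450`` with a
    15 ms (ABR) or 150 ms (AMLR) analysis window.
    """
    if k < 0:
        raise ValueError("deviation must be >= 0 samples")
    return k * WINDOW_MS[subtype] / N_SAMPLES_STANDARD


def _gold_index(gold, label: str) -> int | None:
    if gold is None:
        return None
    if isinstance(gold, Annotation):
        return gold.sample_index(label)
    idx = gold.get(label)
    return None if idx is None else int(idx)


def compute_match_rates(
    pred: list[Annotation],
    gold: list,
    tolerance: int = 4,
    *,
    count_missing_pred_as_miss: bool = True,
    include_gold_na: bool = False,
) -> MatchReport:
    """Score aligned prediction/gold lists.

    *gold* entries may be :class:`Annotation` objects or plain
    label→sample-index mappings (``None`` for a recording without gold).
    Lists must be aligned one-to-one by recording.  A wave is evaluable iff
    gold has it (unless ``include_gold_na``, which also counts gold-NA
    waves, matched only when the prediction is NA too); it is matched iff
    the prediction has it within ±*tolerance* samples.
    """
    if len(pred) != len(gold):
        raise ValueError(
            f"pred and gold are not aligned: {len(pred)} vs {len(gold)} recordings"
        )
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0 samples")
    if not pred:
        raise ValueError("nothing to score")
    subtype = pred[0].subtype
    labels = WAVE_LABELS[subtype]
    n_eval = {label: 0 for label in labels}
    n_match = {label: 0 for label in labels}
    for p, g in zip(pred, gold):
        if p.subtype != subtype:
            raise ValueError("mixed subtypes in prediction list")
        for label in labels:
            g_idx = _gold_index(g, label)
            p_idx = p.sample_index(label)
            if g_idx is None:
                if include_gold_na:
                    n_eval[label] += 1
                    if p_idx is None:
                        n_match[label] += 1
                continue
            n_eval[label] += 1
            if p_idx is None:
                if not count_missing_pred_as_miss:
                    n_eval[label] -= 1
                continue
            if abs(p_idx - g_idx) <= tolerance:
                n_match[label] += 1
    per_wave = {
        label: WaveScore(n_eval[label], n_match[label]) for label in labels
    }
    return MatchReport(subtype=subtype, tolerance_samples=tolerance, per_wave=per_wave)


def deviation_table(
    pred: list[Annotation],
    gold: list,
    tolerance: int = 4,
    recording_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(recording, wave) deviations for review export.

    One row per evaluable wave: predicted and gold indices, deviation in
    samples and ms, and the matched flag.  Mismatches can be filtered from
    this frame for clinician review.
    """
    if len(pred) != len(gold):
        raise ValueError("pred and gold are not aligned")
    if recording_ids is None:
        recording_ids = [p.source_id or str(i) for i, p in enumerate(pred)]
    rows = []
    for rid, p, g in zip(recording_ids, pred, gold):
        labels = WAVE_LABELS[p.subtype]
        for label in labels:
            g_idx = _gold_index(g, label)
            if g_idx is None:
                continue
            p_idx = p.sample_index(label)
            dev = None if p_idx is None else abs(p_idx - g_idx)
            rows.append(
                {
                    "recording": rid,
                    "wave": label,
                    "pred_index": p_idx,
                    "gold_index": g_idx,
                    "deviation_samples": dev,
                    "deviation_ms": (
                        None if dev is None else sample_deviation_to_ms(dev, p.subtype)
                    ),
                    "matched": dev is not None and dev <= tolerance,
                }
            )
    return pd.DataFrame(rows)
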