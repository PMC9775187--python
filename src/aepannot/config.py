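"""YAML configuration: filter settings, extrema window and rule tables.

Every tunable of the pipeline lives here so clinicians can adapt the
normative intervals to their own recording setup without touching code.
``default_config()`` reproduces the built-in defaults; ``save_config`` /
``load_config`` round-trip them through a human-editable YAML file with one
section per subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .annotation import (
    InterWaveRule,
    RuleConfig,
    WaveIntervalRule,
    default_rules,
)
from .eclipse_io import SUBTYPES
from .preprocess import DisplayFilterSpec, default_display_filter

__all__ = ["PipelineConfig", "default_config", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything needed to process one subtype end to end."""

    subtype: str
    display_filter: DisplayFilterSpec
    rules: RuleConfig


def default_config() -> dict[str, PipelineConfig]:
    return {
        st: PipelineConfig(
            subtype=st,
            display_filter=default_display_filter(st),
            rules=default_rules(st),
        )
        for st in SUBTYPES
    }


def _interval_to_dict(rule: WaveIntervalRule) -> dict:
    d = {
        "polarity": rule.polarity,
        "core_ms": list(rule.core_ms),
        "expanded_ms": list(rule.expanded_ms),
    }
    if rule.hard_cap_ms is not None:
        d["hard_cap_ms"] = rule.hard_cap_ms
    return d


def save_config(cfg: dict[str, PipelineConfig], path: str | Path) -> None:
    doc = {}
    for st, pc in cfg.items():
        f = pc.display_filter
        doc[st.lower()] = {
            "display_filter": {
                "low_pass_hz": f.low_pass_hz,
                "high_pass_hz": f.high_pass_hz,
                "fir_order": f.fir_order,
                "butter_order": f.butter_order,
                "zero_phase": f.zero_phase,
            },
            "extrema_window": pc.rules.extrema_window,
            "amplitude_override_ratio": pc.rules.amplitude_override_ratio,
            "exclusivity_guard_ms": pc.rules.exclusivity_guard_ms,
            "constraint_slack_ms": pc.rules.constraint_slack_ms,
            "intervals": {
                lb: _interval_to_dict(r) for lb, r in pc.rules.interval_rules.items()
            },
            "gaps": [
                {
                    "from": g.from_label,
                    "to": g.to_label,
                    "range_ms": list(g.allowed_gap_ms),
                }
                for g in pc.rules.inter_wave_rules
            ],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict[str, PipelineConfig]:
    doc = yaml.safe_load(Path(path).read_text())
    out: dict[str, PipelineConfig] = {}
    for key, section in doc.items():
        subtype = key.upper()
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype section {key!r} in {path}")
        f = section["display_filter"]
        display = DisplayFilterSpec(
            low_pass_hz=float(f["low_pass_hz"]),
            high_pass_hz=float(f["high_pass_hz"]),
            fir_order=int(f.get("fir_order", 100)),
            butter_order=int(f.get("butter_order", 2)),
            zero_phase=bool(f.get("zero_phase", True)),
        )
        intervals = {
            lb: WaveIntervalRule(
                wave_label=lb,
                polarity=d["polarity"],
                core_ms=tuple(d["core_ms"]),
                expanded_ms=tuple(d["expanded_ms"]),
                hard_cap_ms=d.get("hard_cap_ms"),
            )
            for lb, d in section["intervals"].items()
        }
        gaps = [
            InterWaveRule(g["from"], g["to"], tuple(g["range_ms"]))
            for g in section.get("gaps", [])
        ]
        rules = RuleConfig(
            subtype=subtype,
            interval_rules=intervals,
            inter_wave_rules=gaps,
            amplitude_override_ratio=float(
                section.get("amplitude_override_ratio", 1.5)
            ),
            extrema_window=int(section.get("extrema_window", 4)),
            exclusivity_guard_ms=float(section.get("exclusivity_guard_ms", 0.1)),
            constraint_slack_ms=float(section.get("constraint_slack_ms", 0.0)),
        )
        rules.validate()
        out[subtype] = PipelineConfig(subtype, display, rules)
    return out
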