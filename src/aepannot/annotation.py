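"""Interval tables and the rule engine that selects waves of interest.

ABR waveforms are annotated with the five Jewett peaks I–V, AMLR waveforms
with the Na/Nb troughs and Pa/Pb peaks.  Selection is combinatorial and
exclusive: each wave has a normative *core* latency interval and a wider
*expanded* interval (to admit pathological latency shifts), candidates must
respect inter-wave gap constraints against already-resolved anchors, and
core candidates take priority over expanded-only ones unless an
expanded-only candidate is much larger in amplitude.  Waves that cannot be
resolved are reported as NA and the search continues with the remaining
waves.

The default interval tables are reconstructions from normative literature
values (approximate ABR peak latencies 1.5/3.5/5.5 ms for I/III/V; AMLR
ranges Na 18–25, Pa 24–36, Nb 34–47, Pb 55–80 ms with envelope-widened
expansions) — see ``docs/methods.md``.  Every number is configuration, not
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .eclipse_io import ABR, AMLR, WAVE_LABELS
from .extrema import DEFAULT_WINDOW, ExtremaSet, find_local_extrema
from .preprocess import Waveform

__all__ = [
    "PEAK",
    "TROUGH",
    "WaveIntervalRule",
    "InterWaveRule",
    "RuleConfig",
    "WavePick",
    "Annotation",
    "AnnotationContractError",
    "default_rules",
    "default_abr_rules",
    "default_amlr_rules",
    "select_wave",
    "annotate_abr",
    "annotate_amlr",
    "annotate",
]

PEAK = "peak"
TROUGH = "trough"


class AnnotationContractError(ValueError):
    """Waveform handed to an annotator violates its preconditions."""


@dataclass(frozen=True)
class WaveIntervalRule:
    """Latency windows for one wave.

    ``core_ms`` is the normative interval searched with priority;
    ``expanded_ms`` (containing it) admits abnormal latencies;
    ``hard_cap_ms``, when set, is an absolute upper latency bound that even
    the expanded search may not cross (e.g. an ABR peak V after 7 ms is not
    accepted as peak V).
    """

    wave_label: str
    polarity: str  # PEAK or TROUGH
    core_ms: tuple[float, float]
    expanded_ms: tuple[float, float]
    hard_cap_ms: float | None = None

    def validate(self) -> None:
        if self.polarity not in (PEAK, TROUGH):
            raise ValueError(f"bad polarity {self.polarity!r}")
        c0, c1 = self.core_ms
        e0, e1 = self.expanded_ms
        if not (e0 <= c0 <= c1 <= e1):
            raise ValueError(
                f"{self.wave_label}: core {self.core_ms} not inside "
                f"expanded {self.expanded_ms}"
            )

    @property
    def effective_upper_ms(self) -> float:
        if self.hard_cap_ms is None:
            return self.expanded_ms[1]
        return min(self.expanded_ms[1], self.hard_cap_ms)


@dataclass(frozen=True)
class InterWaveRule:
    """Allowed latency gap (``to`` minus ``from``) between two waves, in ms."""

    from_label: str
    to_label: str
    allowed_gap_ms: tuple[float, float]

    def validate(self) -> None:
        lo, hi = self.allowed_gap_ms
        if not 0 < lo <= hi:
            raise ValueError(
                f"{self.from_label}->{self.to_label}: gap bounds must be "
                f"positive and ordered, got {self.allowed_gap_ms}"
            )

    @property
    def midpoint_ms(self) -> float:
        lo, hi = self.allowed_gap_ms
        return (lo + hi) / 2.0


@dataclass(frozen=True)
class ExcludeZones:
    """Latency zones claimed by other waves of the same polarity.

    ``hard`` zones (guarded cores) always disqualify a candidate outside the
    searching wave's own core; ``soft`` zones (the guard margins at core
    edges) disqualify one only while a core candidate exists.
    """

    hard: tuple[tuple[float, float], ...] = ()
    soft: tuple[tuple[float, float], ...] = ()


@dataclass
class RuleConfig:
    """Complete rule set for one subtype.

    ``amplitude_override_ratio`` quantifies "much larger": an expanded-only
    candidate displaces the best core candidate only when its absolute
    amplitude is at least this multiple of the core candidate's.
    """

    subtype: str
    interval_rules: dict[str, WaveIntervalRule]
    inter_wave_rules: list[InterWaveRule] = field(default_factory=list)
    amplitude_override_ratio: float = 1.5
    extrema_window: int = DEFAULT_WINDOW
    #: Exclusivity guard: when wave X is searched, candidates lying inside
    #: another same-polarity wave's core interval (shrunk by this margin at
    #: each end) and outside X's own core are ineligible — each candidate is
    #: claimed by the wave whose normative interval explains it best.
    exclusivity_guard_ms: float = 0.1
    #: Measurement slack applied to inter-wave gap bounds: latencies read
    #: off a filtered, sampled trace jitter by a few samples, so normative
    #: gap limits are not enforced with false precision.
    constraint_slack_ms: float = 0.0

    def validate(self) -> None:
        labels = WAVE_LABELS[self.subtype]
        if set(self.interval_rules) != set(labels):
            raise ValueError(
                f"{self.subtype} needs one interval rule per wave in {labels}"
            )
        for rule in self.interval_rules.values():
            rule.validate()
        for rule in self.inter_wave_rules:
            rule.validate()
        if self.amplitude_override_ratio <= 1:
            raise ValueError("amplitude_override_ratio must exceed 1")

    def gap_rule(self, from_label: str, to_label: str) -> InterWaveRule | None:
        for rule in self.inter_wave_rules:
            if rule.from_label == from_label and rule.to_label == to_label:
                return rule
        return None


@dataclass(frozen=True)
class WavePick:
    """A resolved wave: extremum sample index, latency and amplitude."""

    sample_index: int
    latency_ms: float
    amplitude_uv: float


@dataclass
class Annotation:
    """Per-wave picks (or ``None`` for NA) for one recording."""

    subtype: str
    waves: dict[str, WavePick | None]
    source_id: str = ""

    def present(self) -> list[str]:
        return [lb for lb in WAVE_LABELS[self.subtype] if self.waves.get(lb)]

    def sample_index(self, label: str) -> int | None:
        pick = self.waves.get(label)
        return None if pick is None else pick.sample_index

    def latency_ms(self, label: str) -> float | None:
        pick = self.waves.get(label)
        return None if pick is None else pick.latency_ms


# ---------------------------------------------------------------------------
# Default rule tables (reconstructed normative values; all configurable)

_ABR_CENTERS = {"I": 1.5, "II": 2.5, "III": 3.5, "IV": 4.5, "V": 5.5}
ABR_V_HARD_CAP_MS = 7.0
_ABR_CORE_HALF_MS = 0.5
_ABR_EXPANDED_HALF_MS = 1.0


def default_abr_rules() -> RuleConfig:
    intervals = {}
    for label, center in _ABR_CENTERS.items():
        intervals[label] = WaveIntervalRule(
            wave_label=label,
            polarity=PEAK,
            core_ms=(center - _ABR_CORE_HALF_MS, center + _ABR_CORE_HALF_MS),
            expanded_ms=(
                center - _ABR_EXPANDED_HALF_MS,
                center + _ABR_EXPANDED_HALF_MS,
            ),
            hard_cap_ms=ABR_V_HARD_CAP_MS if label == "V" else None,
        )
    gaps = [
        # the ~2 ms expected interpeak spacing, with ±1 ms slack
        InterWaveRule("I", "III", (1.0, 3.0)),
        InterWaveRule("III", "V", (1.0, 3.0)),
        # I->V is of the order of 4 ms
        InterWaveRule("I", "V", (3.0, 5.0)),
    ]
    cfg = RuleConfig(ABR, intervals, gaps, constraint_slack_ms=0.1)
    cfg.validate()
    return cfg


def default_amlr_rules() -> RuleConfig:
    intervals = {
        "Na": WaveIntervalRule("Na", TROUGH, (18.0, 25.0), (12.0, 30.0)),
        "Pa": WaveIntervalRule("Pa", PEAK, (24.0, 36.0), (21.0, 45.0)),
        "Nb": WaveIntervalRule("Nb", TROUGH, (34.0, 47.0), (34.0, 56.26)),
        "Pb": WaveIntervalRule("Pb", PEAK, (55.0, 80.0), (46.25, 90.0)),
    }
    gaps = [
        InterWaveRule("Na", "Pa", (7.5, 18.75)),  # literature value, as printed
        InterWaveRule("Pa", "Nb", (4.0, 20.0)),
        InterWaveRule("Nb", "Pb", (8.0, 40.0)),
        InterWaveRule("Pa", "Pb", (15.0, 55.0)),
    ]
    cfg = RuleConfig(AMLR, intervals, gaps, constraint_slack_ms=1.0)
    cfg.validate()
    return cfg


def default_rules(subtype: str) -> RuleConfig:
    return default_abr_rules() if subtype == ABR else default_amlr_rules()


# ---------------------------------------------------------------------------
# Candidate selection

def build_exclude_zones(
    cfg: RuleConfig, label: str, resolved: set[str] = frozenset()
) -> ExcludeZones:
    """Zones claimed by competing same-polarity waves of *label*'s subtype.

    Only *unresolved* competitors claim territory: once a wave has been
    located its claim collapses to the picked extremum itself, so a
    neighbour's search may use the rest of its interval.  Each competing
    wave's core interval, shrunk by ``exclusivity_guard_ms`` at both ends,
    forms a hard zone; the guard margins themselves form soft zones
    (ambiguous territory at a shared core boundary, yielded only when the
    searching wave has an unambiguous core candidate of its own).
    """
    guard = cfg.exclusivity_guard_ms
    hard: list[tuple[float, float]] = []
    soft: list[tuple[float, float]] = []
    polarity = cfg.interval_rules[label].polarity
    for other, r in cfg.interval_rules.items():
        if other == label or r.polarity != polarity or other in resolved:
            continue
        clo, chi = r.core_ms
        zlo, zhi = clo + guard, chi - guard
        if zlo < zhi:
            hard.append((zlo, zhi))
            if guard > 0:
                soft.append((clo, zlo))
                soft.append((zhi, chi))
        else:
            soft.append((clo, chi))
    return ExcludeZones(hard=tuple(hard), soft=tuple(soft))


def select_wave(
    candidates: ExtremaSet,
    w: Waveform,
    rule: WaveIntervalRule,
    constraints: list[tuple[float | None, InterWaveRule]] = (),
    cfg: RuleConfig | None = None,
    *,
    gap_reference: tuple[float, InterWaveRule] | None = None,
    latency_bounds: tuple[float | None, float | None] = (None, None),
    exclude_zones: ExcludeZones | None = None,
    exclude_indices: frozenset[int] | set[int] = frozenset(),
    trace: list | None = None,
) -> int | None:
    """Pick the extremum for one wave, or ``None`` (NA) if nothing qualifies.

    Feasible candidates have the rule's polarity, a latency inside the
    expanded interval (respecting the hard cap and optional exclusive
    *latency_bounds*), and satisfy every constraint whose anchor latency is
    resolved (``None`` anchors are skipped).  *exclude_zones* implement
    candidate exclusivity between waves: a candidate inside a hard zone
    (another wave's guarded core) is always ineligible unless it lies in
    this rule's own core; one inside a soft zone (the guard margin at a
    neighbouring core's edge) is ineligible only while a core candidate
    exists, so that a wave genuinely shifted just past its own interval can
    still be rescued when nothing inside the core explains the recording.

    Scoring: core-interval candidates take priority.  Without a
    *gap_reference*, the extreme amplitude wins (maximum for peaks, minimum
    for troughs), except that an expanded-only candidate overrides the core
    choice when its absolute amplitude is at least
    ``amplitude_override_ratio`` times the core candidate's.  With a
    *gap_reference*, candidates minimise the distance between their gap to
    the reference anchor and the midpoint of that rule's allowed gap —
    time-related conditions outrank amplitude-related ones, so no amplitude
    override applies and amplitude only breaks ties.  Remaining ties break
    by earliest latency.
    """
    ratio = cfg.amplitude_override_ratio if cfg is not None else 1.5
    slack = cfg.constraint_slack_ms if cfg is not None else 0.0
    t = w.times_ms
    amps = w.amplitudes
    lo = rule.expanded_ms[0]
    hi = rule.effective_upper_ms
    core_lo, core_hi = rule.core_ms
    hard_zones = exclude_zones.hard if exclude_zones else ()
    soft_zones = exclude_zones.soft if exclude_zones else ()

    feasible: list[int] = []
    soft_flag: dict[int, bool] = {}
    for i in candidates.of_polarity(rule.polarity):
        if int(i) in exclude_indices:
            continue
        lat = t[i]
        if not lo <= lat <= hi:
            continue
        lb, ub = latency_bounds
        if lb is not None and not lat > lb:
            continue
        if ub is not None and not lat < ub:
            continue
        in_own_core = core_lo <= lat <= core_hi
        if not in_own_core and any(zlo <= lat <= zhi for zlo, zhi in hard_zones):
            continue
        # soft-zone membership marks ambiguity even on a shared core boundary
        soft = any(zlo <= lat <= zhi for zlo, zhi in soft_zones)
        ok = True
        for anchor_lat, grule in constraints:
            if anchor_lat is None:
                continue
            if grule.to_label == rule.wave_label:
                gap = lat - anchor_lat
            elif grule.from_label == rule.wave_label:
                gap = anchor_lat - lat
            else:  # constraint does not involve this wave
                continue
            glo, ghi = grule.allowed_gap_ms
            if not glo - slack <= gap <= ghi + slack:
                ok = False
                break
        if ok:
            feasible.append(int(i))
            soft_flag[int(i)] = soft

    if trace is not None:
        trace.append(
            {
                "wave": rule.wave_label,
                "feasible": [(int(i), float(t[i]), float(amps[i])) for i in feasible],
            }
        )
    if not feasible:
        return None

    sign = 1.0 if rule.polarity == PEAK else -1.0

    def amp_key(i: int):
        # larger signed extreme first, earliest latency breaks ties
        return (-sign * amps[i], t[i])

    def gap_key(i: int):
        anchor_lat, grule = gap_reference
        if grule.to_label == rule.wave_label:
            gap = t[i] - anchor_lat
        else:
            gap = anchor_lat - t[i]
        return (abs(gap - grule.midpoint_ms), -sign * amps[i], t[i])

    core = [i for i in feasible if core_lo <= t[i] <= core_hi]
    if any(not soft_flag[i] for i in core):
        # soft-zone candidates yield to an unambiguous core explanation
        feasible = [i for i in feasible if not soft_flag[i]]
        core = [i for i in feasible if core_lo <= t[i] <= core_hi]
    expanded_only = [i for i in feasible if i not in core]

    def signed(i):
        # amplitude in the wave's polarity direction; filter undershoot can
        # push an extremum across zero, so "larger" must be signed
        return sign * amps[i]

    def biggest(pool):
        return min(pool, key=lambda i: (-signed(i), t[i]))

    def much_larger(big, choice):
        if signed(big) <= 0:
            return False
        if signed(choice) <= 0:
            return True
        return signed(big) >= ratio * signed(choice)

    if gap_reference is None:
        if not core:
            choice = min(feasible, key=amp_key)
        else:
            choice = min(core, key=amp_key)
            if expanded_only:
                big = biggest(expanded_only)
                if much_larger(big, choice):
                    choice = big
    else:
        pool = core if core else feasible
        choice = min(pool, key=gap_key)
        big = biggest(pool)
        if much_larger(big, choice):
            choice = big
    if trace is not None:
        trace[-1]["selected"] = int(choice)
    return choice


def _check_input(w: Waveform, subtype: str) -> None:
    if w.subtype != subtype:
        raise AnnotationContractError(
            f"expected a {subtype} waveform, got {w.subtype}"
        )
    if not w.filtered:
        raise AnnotationContractError(
            "waveform must pass apply_display_filters before annotation"
        )


def _pick(w: Waveform, idx: int | None) -> WavePick | None:
    if idx is None:
        return None
    return WavePick(
        sample_index=int(idx),
        latency_ms=float(w.times_ms[idx]),
        amplitude_uv=float(w.amplitudes[idx]),
    )


def annotate_abr(
    w: Waveform,
    ex: ExtremaSet | None = None,
    cfg: RuleConfig | None = None,
    trace: list | None = None,
) -> Annotation:
    """Annotate an ABR waveform with Jewett peaks I–V.

    The three clinically interpreted peaks are resolved sequentially —
    first I, then III, then V — over non-overlapping core intervals, each
    by maximum amplitude among the candidates that satisfy the interpeak
    gap constraints against the already-resolved anchors (skipped when the
    anchor is NA).  Candidate exclusivity keeps one wave's search from
    claiming an extremum lying squarely in another wave's core interval.
    Waves II and IV are assisting waves, searched afterwards strictly
    between their resolved neighbours; failing to find them never
    invalidates I, III or V.
    """
    if cfg is None:
        cfg = default_abr_rules()
    cfg.validate()
    _check_input(w, ABR)
    if ex is None:
        ex = find_local_extrema(w, cfg.extrema_window)

    rules = cfg.interval_rules
    t = w.times_ms
    found: dict[str, int | None] = {}

    def lat(label: str) -> float | None:
        idx = found.get(label)
        return None if idx is None else float(t[idx])

    def cons(pairs: list[tuple[str, str]]):
        # pairs are (anchor wave, wave being selected); NA anchors are skipped
        out = []
        for anchor, target in pairs:
            grule = cfg.gap_rule(anchor, target)
            if grule is not None and lat(anchor) is not None:
                out.append((lat(anchor), grule))
        return out

    def zones(label: str) -> ExcludeZones:
        resolved = {lb for lb, idx in found.items() if idx is not None}
        return build_exclude_zones(cfg, label, resolved)

    def taken() -> frozenset[int]:
        return frozenset(idx for idx in found.values() if idx is not None)

    found["I"] = select_wave(
        ex, w, rules["I"], [], cfg, exclude_zones=zones("I"), trace=trace
    )
    found["III"] = select_wave(
        ex, w, rules["III"], cons([("I", "III")]), cfg,
        exclude_zones=zones("III"), exclude_indices=taken(), trace=trace,
    )
    found["V"] = select_wave(
        ex, w, rules["V"], cons([("I", "V"), ("III", "V")]), cfg,
        exclude_zones=zones("V"), exclude_indices=taken(), trace=trace,
    )
    # assisting waves, strictly between their neighbours
    found["II"] = select_wave(
        ex, w, rules["II"], [], cfg,
        latency_bounds=(lat("I"), lat("III")),
        exclude_zones=zones("II"), exclude_indices=taken(), trace=trace,
    )
    found["IV"] = select_wave(
        ex, w, rules["IV"], [], cfg,
        latency_bounds=(lat("III"), lat("V")),
        exclude_zones=zones("IV"), exclude_indices=taken(), trace=trace,
    )
    waves = {label: _pick(w, found.get(label)) for label in WAVE_LABELS[ABR]}
    return Annotation(subtype=ABR, waves=waves, source_id=w.source_id)


def annotate_amlr(
    w: Waveform,
    ex: ExtremaSet | None = None,
    cfg: RuleConfig | None = None,
    trace: list | None = None,
) -> Annotation:
    """Annotate an AMLR waveform with Na, Pa, Nb and Pb.

    Pa — the basal, most robust component — is located first, by maximum
    amplitude within its intervals.  If Pa cannot be found the whole
    annotation is NA.  The remaining waves are then resolved relative to
    Pa with time-distance priority: Na as the preceding trough whose
    Na→Pa gap lies in the configured range, Nb as the following trough,
    and Pb after Nb (after Pa alone when Nb is NA), each scored by
    proximity of its gap to the gap rule's midpoint rather than by
    amplitude.
    """
    if cfg is None:
        cfg = default_amlr_rules()
    cfg.validate()
    _check_input(w, AMLR)
    if ex is None:
        ex = find_local_extrema(w, cfg.extrema_window)

    rules = cfg.interval_rules
    t = w.times_ms
    labels = WAVE_LABELS[AMLR]

    pa = select_wave(ex, w, rules["Pa"], [], cfg, trace=trace)
    if pa is None:
        return Annotation(
            subtype=AMLR, waves={lb: None for lb in labels}, source_id=w.source_id
        )
    lat_pa = float(t[pa])

    r_na_pa = cfg.gap_rule("Na", "Pa")
    na = select_wave(
        ex, w, rules["Na"], [(lat_pa, r_na_pa)], cfg,
        gap_reference=(lat_pa, r_na_pa), latency_bounds=(None, lat_pa), trace=trace,
    )
    r_pa_nb = cfg.gap_rule("Pa", "Nb")
    nb = select_wave(
        ex, w, rules["Nb"], [(lat_pa, r_pa_nb)], cfg,
        gap_reference=(lat_pa, r_pa_nb), latency_bounds=(lat_pa, None), trace=trace,
    )
    r_nb_pb = cfg.gap_rule("Nb", "Pb")
    r_pa_pb = cfg.gap_rule("Pa", "Pb")
    if nb is not None:
        lat_nb = float(t[nb])
        pb = select_wave(
            ex, w, rules["Pb"],
            [(lat_nb, r_nb_pb), (lat_pa, r_pa_pb)], cfg,
            gap_reference=(lat_nb, r_nb_pb), latency_bounds=(lat_nb, None),
            trace=trace,
        )
    else:
        pb = select_wave(
            ex, w, rules["Pb"], [(lat_pa, r_pa_pb)], cfg,
            gap_reference=(lat_pa, r_pa_pb), latency_bounds=(lat_pa, None),
            trace=trace,
        )

    found = {"Na": na, "Pa": pa, "Nb": nb, "Pb": pb}
    waves = {label: _pick(w, found[label]) for label in labels}
    return Annotation(subtype=AMLR, waves=waves, source_id=w.source_id)


def annotate(
    w: Waveform,
    ex: ExtremaSet | None = None,
    cfg: RuleConfig | None = None,
    trace: list | None = None,
) -> Annotation:
    """Dispatch to the ABR or AMLR annotator by waveform subtype."""
    if w.subtype == ABR:
        return annotate_abr(w, ex, cfg, trace)
    return annotate_amlr(w, ex, cfg, trace)
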