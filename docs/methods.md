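# Methods

This note documents the models, rules and numerical choices behind
`aepannot`: what the annotators assume, what every tunable means, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Signal model and preprocessing

A recording is a 450-sample stimulus-locked epoch stored as two interleaved
sweep sub-averages (buffers A and B) in raw device units.  The analysis
waveform is their mean, scaled to microvolts; averaging two buffers with
independent noise reduces the residual-noise standard deviation by √2.
Sample 0 corresponds to stimulus completion (the device starts the stimulus
before sampling), so the time axis is simply `t_i = 1000·i/f_s` ms —
`PrestimulusSamples` is carried as metadata only.  At the standard
geometry, 450 samples at 30 kHz span the 15 ms ABR window and 450 samples
at 3 kHz span the 150 ms AMLR window; one sample is therefore 1/30 ms (ABR)
or 1/3 ms (AMLR).

Clinicians do not annotate the raw average: they view it through *visual
display filters* (VDFs) that band-limit the trace beyond the acquisition
filters.  The annotator therefore runs on the VDF-filtered trace.

**Display filters.**  Low-pass: windowed linear-phase FIR (order 100, i.e.
101 taps, Hamming window); high-pass: Butterworth (order 2).  Defaults per
subtype: ABR 150–1500 Hz, AMLR 15–100 Hz.  Both are applied
forward–backward (`zero_phase: true`) so that filter group delay cannot
shift latencies — the measured quantity; a causal mode is retained for
fidelity experiments.  Filter orders are conventional, stable choices; they
are configuration, not contract.  Edge transients are suppressed by
reflect-padding about three filter lengths before filtering.  Note that the
hardware acquisition filters (33 Hz/1500 Hz ABR, 10 Hz/1500 Hz AMLR) shape
the recorded data and are *not* part of this display pipeline; the
synthetic generator does not model them.

A consequence worth understanding: zero-phase band-limiting of a burst of
nearby bumps depresses the baseline between them (high-pass undershoot) and
can displace individual extrema by a few samples relative to the unfiltered
shape.  This is physics, not a defect — clinicians see, and mark, the same
filtered trace — and it drives several rule-design choices below.

## Candidate extrema

A sample is a candidate *peak* if it is the maximum of a ±m-sample window
(boundary windows truncated) and strictly exceeds at least one immediate
neighbour; exact-tie plateaus report their earliest sample; troughs are
peaks of the negated trace.  This suppresses the small residual-noise
wiggles that survive averaging.  Default `m = 4` samples (0.13 ms ABR,
1.33 ms AMLR), configurable per subtype; the window is deliberately small —
selection, not detection, is where discrimination happens.

## Rule-based wave selection

Each wave of interest has a `WaveIntervalRule`: a normative **core**
latency interval, a containing **expanded** interval that admits
pathological latency shifts (prolonged/shortened latencies occur with
hearing loss and other conditions), and optionally a **hard cap** — an ABR
peak after 7 ms is not accepted as wave V no matter what.  `InterWaveRule`s
bound the latency gaps between wave pairs.  Defaults (all reconstructions
from normative literature values, clearly overridable in config):

| subtype | wave | polarity | core (ms) | expanded (ms) |
|---|---|---|---|---|
| ABR | I | peak | 1.0–2.0 | 0.5–2.5 |
| ABR | II | peak | 2.0–3.0 | 1.5–3.5 |
| ABR | III | peak | 3.0–4.0 | 2.5–4.5 |
| ABR | IV | peak | 4.0–5.0 | 3.5–5.5 |
| ABR | V | peak | 5.0–6.0 | 4.5–6.5, cap 7.0 |
| AMLR | Na | trough | 18–25 | 12–30 |
| AMLR | Pa | peak | 24–36 | 21–45 |
| AMLR | Nb | trough | 34–47 | 34–56.26 |
| AMLR | Pb | peak | 55–80 | 46.25–90 |

ABR cores are ±0.5 ms around the textbook centers 1.5/2.5/3.5/4.5/5.5 ms;
expansions ±1.0 ms.  AMLR cores are the published normative ranges of the
primary source; expansions are the envelope of three partially conflicting
literature sources (plus a 10 ms extension for the inconsistently-present
Pb).  Gap rules: I→III and III→V in [1, 3] ms (±1 ms around the expected
2 ms interpeak), I→V in [3, 5] ms; Na→Pa in [7.50, 18.75] ms as published;
Pa→Nb [4, 20], Nb→Pb [8, 40] and Pa→Pb [15, 55] ms are this package's own
reconstructions from the interval envelopes (no published values exist).

**Selection (`select_wave`).**  Feasible candidates have the right
polarity, lie in the expanded interval (under the cap), and satisfy every
gap constraint whose anchor is resolved (NA anchors are skipped).  Core
candidates take priority over expanded-only ones.  Two scoring modes:

* *Amplitude mode* (ABR waves; AMLR Pa): the extreme amplitude wins —
  maximum for peaks, minimum for troughs — except that an expanded-only
  candidate whose amplitude is **much larger** (≥ `amplitude_override_ratio`,
  default 1.5, times the core best) overrides the core choice.
* *Gap-proximity mode* (AMLR Na/Nb/Pb): time-related conditions outrank
  amplitude-related ones.  Candidates minimise the distance between their
  gap to the anchor (Pa, or Nb for Pb) and the midpoint of the allowed gap;
  amplitude breaks ties.  The same "much larger" override applies: a
  candidate ≥ 1.5× the time-proximal pick's amplitude wins.  Without the
  override, low-amplitude high-pass rebound bumps that happen to sit near
  the expected gap would beat genuine waves.

Amplitude comparisons are **signed in the wave's polarity direction**:
filter undershoot can push an extremum below zero, and a below-zero "peak"
must never override a genuine positive one.  Remaining ties break by
earliest latency (deterministic; consistent with time priority).

**Candidate exclusivity.**  Conditions are combinatorial and *exclusive*:
when wave X is searched, candidates lying inside another same-polarity,
still-unresolved wave's core interval are ineligible unless they also lie
in X's own core — an extremum squarely in II's territory cannot be claimed
by I's or III's expanded search.  Competitor cores are shrunk by an
`exclusivity_guard_ms` margin (default 0.1 ms) at each end; the margins are
"soft": a candidate there yields only when X has an unambiguous core
candidate of its own, so a wave genuinely shifted just past its interval
can still be rescued.  Once a wave is resolved, its claim collapses to the
picked sample itself.  Without exclusivity, the filtered baseline
depression lets a large wave II "much-larger-override" the true wave I or
III — the dominant failure mode in development benchmarks.

**Gap slack.**  Gap bounds come from normative tables in milliseconds, but
gaps are measured between extrema of a filtered, sampled trace and jitter
by a few samples.  Constraints are therefore applied with a small
measurement slack (`constraint_slack_ms`: 0.1 ms ABR, 1.0 ms AMLR — about
3 samples each) rather than as exact inequalities.

**ABR flow.**  I, then III (constrained by I→III), then V (I→V, III→V) —
their intervals do not overlap by construction.  Waves II and IV are
assisting waves, searched afterwards strictly between their resolved
neighbours; failing to find them never invalidates I/III/V.

**AMLR flow.**  Pa — the basal, most robust component — first, by maximum
amplitude within its intervals (so a large peak near 15 ms is *not* taken
for Pa: it is outside the interval).  Pa NA blanks the whole annotation.
Then Na (preceding trough, Na→Pa gap), Nb (following trough, Pa→Nb gap),
and Pb after Nb — or after Pa alone when Nb is NA, using the Pa→Pb gap
rule; this fallback is this package's decision where published behaviour is
only implied.

## PAM artifact screening

The post-auricular-muscle reflex contaminates AMLR as a sharp spike at
13–15 ms — before Pa — with amplitude much larger than Pa's.  Detection:
any extremum inside `pam_window_ms` (default [13, 15]) whose absolute
amplitude is ≥ `pam_ratio` (default 2.0, "much larger" being unquantified
in the literature) times the reference — Pa's amplitude when annotated,
else the largest absolute amplitude in the Pa core interval, else the
waveform RMS.  Spike sharpness is not separately tested: the narrow window
plus the amplitude ratio is the operational criterion.  Screening is
algorithmic here; `evaluate --exclude-pam` drops flagged recordings before
scoring and reports the count.

## Scoring

A predicted wave matches when it deviates from the gold position by at most
`tolerance` samples (default 4 — 0.13 ms ABR, 1.33 ms AMLR), inclusive;
this absorbs both cursor imprecision in manual gold marks and small
filter-induced displacement.  Waves absent from the gold standard are
excluded from the denominator; a gold wave the predictor missed counts as
unmatched (both behaviours are flags, chosen so rates read as
sensitivity-like quantities).  Match rates are invariant to recording order
and monotone in the tolerance.

## Synthetic data: what it emulates, and what it does not

`generate_recording` renders a clean template as a sum of Gaussian
components (negative amplitude = trough) on the standard 450-sample axis,
then adds independent Gaussian noise to each buffer.  Ground truth is the
extremum of the clean template nearest each component (search window
±1.5σ, clipped to half the distance to the nearest *same-polarity*
component; a non-extremal pick signals merged components and warns).
`generate_benchmark` draws per-recording latencies uniformly inside the
rule tables' core intervals, rejected (cap 1000 tries) until all gap rules
and a minimum separation hold, with amplitudes uniform per wave and fixed
widths.

Defaults, chosen once as representative of the physiology and the stated
recording setup:

* **ABR**: widths σ = 0.25 ms; amplitudes I–IV 0.2–0.4 µV, V 0.4–0.5 µV
  (responses are sub-microvolt; V is canonically the most robust peak);
  buffer noise SD 0.05 µV; minimum consecutive separation 0.8 ms (clinical
  interpeak spacing is ≈1 ms; closer σ=0.25 ms bumps would merge).
* **AMLR**: widths σ = 3 ms; amplitudes Pa 1.0–1.5 µV (largest), Na/Nb
  −0.5 to −1.0 µV, Pb 0.5–1.0 µV; buffer noise SD 0.1 µV.
* **PAM spikes**: amplitude 3–6× the recording's Pa, σ = 2 ms, centered at
  13.5–14.5 ms.  The width is chosen so a "sharp" spike retains most of its
  amplitude through the 100 Hz display low-pass while remaining far briefer
  than any AMLR component; centers keep the whole spike inside the
  characteristic 13–15 ms range.

The generator emulates component morphology, normative latency dispersion,
two-buffer noise and the PAM artifact.  It does **not** emulate: the
acquisition-filter chain, non-Gaussian wave shapes (real waves are
asymmetric), amplitude–latency correlations, hearing-loss-dependent latency
shifts, absent waves (every benchmark recording contains all waves of its
subtype), electrode/movement artifacts other than PAM, or inter-clinician
gold-standard disagreement.  Passing benchmarks therefore demonstrate that
the rule engine recovers waves under normative dispersion, realistic
amplitudes and averaging noise — not that it matches clinicians on
abnormal or grey-zone clinical recordings.

## Verification strategy and numerical choices

* The test suite checks every operation against independent oracles: a
  brute-force O(n·m) windowed-max scan for extrema, the designed filters'
  analytic frequency response for the time-domain filter path, a
  double-loop scorer for match rates, Monte-Carlo variance halving for
  buffer averaging, and hypothesis-generated round-trips for the XML
  dialect (floats serialized at 17 significant digits, exact for IEEE
  doubles).
* Clean-signal recovery is asserted against component extrema of the
  *display-filtered* clean template (`synth.component_extrema`): zero-phase
  band-limiting displaces AMLR extrema by up to ~1 ms relative to the
  unfiltered template, which is filter physics rather than selection error;
  on that oracle the annotators recover 100% of planted components within
  ±1 sample on noise-free benchmarks.  The ±4-sample benchmark scores
  against the unfiltered-template gold and absorbs the displacement.
* Benchmarks use 300 recordings per subtype (seed 42 in the tests), sized
  so every match-rate percentage rests on ≥300 Bernoulli trials while the
  whole suite runs in seconds.
* Determinism: the engine contains no randomness; all generator randomness
  flows from a single seed per recording/benchmark.

## Known limitations

* All interval/gap defaults are literature reconstructions, not the
  (unpublished) tuned values of any specific clinical deployment; sites
  with different stimuli or populations should adjust the config.
* The annotators assume the standard 450-sample geometry only for the
  ms↔sample conversions in reporting and scoring; rules operate in ms and
  work at other rates, but defaults were validated at 30 kHz/3 kHz.
* No amplitude floor: in a waveform with no real response the rules may
  still label small ripple extrema (clinical response-presence judgement is
  out of scope).
* PAM screening keys on amplitude ratio within a fixed window; a PAM reflex
  atypically late, or barely larger than Pa, evades it.
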