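import numpy as np
import pytest

from aepannot import (
    ABR,
    AMLR,
    WAVE_LABELS,
    annotate,
    annotate_abr,
    annotate_amlr,
    apply_display_filters,
    average_buffers,
    find_local_extrema,
    select_wave,
)
from aepannot.annotation import (
    AnnotationContractError,
    InterWaveRule,
    WaveIntervalRule,
    default_abr_rules,
    default_amlr_rules,
)
from aepannot.preprocess import Waveform
from aepannot.synth import component_extrema
import aepannot.synth as synth


class TestSelectWave:
    """The core/expanded priority rule with the amplitude override."""

    def _setup(self, make_waveform, core_amp, expanded_amp):
        # candidates at 1.6 ms (core of wave I) and 2.3 ms (expanded only)
        w = make_waveform(
            ABR, [(1.6, core_amp, 0.1), (2.3, expanded_amp, 0.1)], filtered="flag"
        )
        ex = find_local_extrema(w, 4)
        return w, ex, default_abr_rules()

    def test_modest_expanded_candidate_loses_to_core(self, make_waveform):
        w, ex, cfg = self._setup(make_waveform, 0.30, 0.36)
        idx = select_wave(ex, w, cfg.interval_rules["I"], [], cfg)
        assert w.times_ms[idx] == pytest.approx(1.6, abs=0.05)

    def test_much_larger_expanded_candidate_overrides(self, make_waveform):
        w, ex, cfg = self._setup(make_waveform, 0.30, 0.70)
        idx = select_wave(ex, w, cfg.interval_rules["I"], [], cfg)
        assert w.times_ms[idx] == pytest.approx(2.3, abs=0.05)

    def test_empty_window_returns_na(self, make_waveform):
        w = make_waveform(ABR, [(10.0, 0.4, 0.2)], filtered="flag")
        ex = find_local_extrema(w, 4)
        cfg = default_abr_rules()
        assert select_wave(ex, w, cfg.interval_rules["I"], [], cfg) is None

    def test_inter_wave_constraint_filters_candidates(self, make_waveform):
        w = make_waveform(ABR, [(3.1, 0.4, 0.1), (3.8, 0.2, 0.1)], filtered="flag")
        ex = find_local_extrema(w, 4)
        cfg = default_abr_rules()
        rule = cfg.interval_rules["III"]
        # anchor I at 1.5 ms; require gap in [2.0, 3.0]: only 3.8 qualifies
        cons = [(1.5, InterWaveRule("I", "III", (2.0, 3.0)))]
        idx = select_wave(ex, w, rule, cons, cfg)
        assert w.times_ms[idx] == pytest.approx(3.8, abs=0.05)

    def test_hard_cap_excludes_late_candidate(self, make_waveform):
        rule = WaveIntervalRule("V", "peak", (5.0, 6.0), (4.5, 8.0), hard_cap_ms=7.0)
        cfg = default_abr_rules()
        w = make_waveform(ABR, [(7.5, 0.5, 0.1)], filtered="flag")
        ex = find_local_extrema(w, 4)
        assert select_wave(ex, w, rule, [], cfg) is None
        w2 = make_waveform(ABR, [(6.8, 0.5, 0.1)], filtered="flag")
        ex2 = find_local_extrema(w2, 4)
        idx = select_wave(ex2, w2, rule, [], cfg)
        assert w2.times_ms[idx] == pytest.approx(6.8, abs=0.05)


class TestAnnotateAbr:
    def test_clean_textbook_peaks_recovered(self, make_waveform):
        w = make_waveform(
            ABR, [(1.5, 0.3, 0.25), (3.5, 0.3, 0.25), (5.5, 0.45, 0.25)]
        )
        ann = annotate_abr(w)
        for label, expect in (("I", 1.5), ("III", 3.5), ("V", 5.5)):
            # within one sample (1/30 ms) of the planted latency
            assert ann.latency_ms(label) == pytest.approx(expect, abs=1.01 / 30)
        # assisting waves, if any filter ripple qualifies, stay ordered
        lats = [ann.latency_ms(lb) for lb in ann.present()]
        assert lats == sorted(lats)

    def test_all_zero_waveform_gives_all_na(self):
        w = Waveform(ABR, np.zeros(450), 30000.0, filtered=True)
        ann = annotate_abr(w)
        assert ann.present() == []

    def test_assisting_waves_found_between_neighbours(self, make_waveform):
        w = make_waveform(
            ABR,
            [(1.5, 0.3, 0.2), (2.5, 0.25, 0.2), (3.5, 0.3, 0.2),
             (4.5, 0.25, 0.2), (5.5, 0.45, 0.2)],
        )
        ann = annotate_abr(w)
        assert ann.present() == ["I", "II", "III", "IV", "V"]
        lats = [ann.latency_ms(lb) for lb in WAVE_LABELS[ABR]]
        assert lats == sorted(lats)

    def test_unfiltered_input_rejected(self, make_waveform):
        w = make_waveform(ABR, [(1.5, 0.3, 0.25)], filtered=False)
        with pytest.raises(AnnotationContractError):
            annotate_abr(w)

    def test_wrong_subtype_rejected(self, make_waveform):
        w = make_waveform(AMLR, [(30.0, 1.0, 3.0)])
        with pytest.raises(AnnotationContractError):
            annotate_abr(w)


class TestAnnotateAmlr:
    def test_clean_textbook_components_recovered(self, make_waveform):
        w = make_waveform(
            AMLR,
            [(20.0, -0.8, 3.0), (30.0, 1.2, 3.0), (40.0, -0.8, 3.0), (60.0, 0.8, 3.0)],
            filtered="flag",  # exact template: recovery within one sample
        )
        ann = annotate_amlr(w)
        for label, expect in (("Na", 20.0), ("Pa", 30.0), ("Nb", 40.0), ("Pb", 60.0)):
            assert ann.latency_ms(label) == pytest.approx(expect, abs=1.01 / 3)

    def test_pa_chosen_by_interval_not_by_amplitude(self, make_waveform):
        # the 15 ms peak is larger, but lies outside the Pa interval
        w = make_waveform(AMLR, [(15.0, 2.0, 3.0), (27.0, 1.0, 3.0)])
        ann = annotate_amlr(w)
        assert ann.latency_ms("Pa") == pytest.approx(27.0, abs=1.5)

    def test_all_zero_waveform_gives_all_na(self):
        w = Waveform(AMLR, np.zeros(450), 3000.0, filtered=True)
        ann = annotate_amlr(w)
        assert ann.present() == []

    def test_missing_pa_blanks_everything(self, make_waveform):
        # a lone trough: no peak anywhere near the Pa window
        w = make_waveform(AMLR, [(20.0, -0.8, 3.0)], filtered="flag")
        ann = annotate_amlr(w)
        assert ann.present() == []

    def test_pb_found_after_pa_when_nb_missing(self, make_waveform):
        from dataclasses import replace

        cfg = default_amlr_rules()
        # narrow the Nb window so the inter-peak dip cannot qualify as Nb
        cfg.interval_rules = dict(cfg.interval_rules)
        cfg.interval_rules["Nb"] = replace(
            cfg.interval_rules["Nb"], core_ms=(34.0, 35.0), expanded_ms=(34.0, 35.0)
        )
        w = make_waveform(
            AMLR, [(20.0, -0.8, 3.0), (30.0, 1.2, 3.0), (62.0, 0.8, 3.0)],
            filtered="flag",
        )
        ann = annotate_amlr(w, cfg=cfg)
        assert ann.waves["Nb"] is None
        # fallback search anchored on Pa alone still locates Pb
        assert ann.latency_ms("Pb") == pytest.approx(62.0, abs=1.5)


class TestEngineProperties:
    @pytest.fixture(scope="class")
    def annotated_benchmark(self):
        out = {}
        for st in (ABR, AMLR):
            recs, _ = synth.generate_benchmark(40, st, seed=11)
            triples = []
            for rec in recs:
                w = apply_display_filters(average_buffers(rec))
                ex = find_local_extrema(w)
                triples.append((w, ex, annotate(w, ex)))
            out[st] = triples
        return out

    def test_present_waves_strictly_ordered(self, annotated_benchmark):
        for triples in annotated_benchmark.values():
            for _, _, ann in triples:
                lats = [ann.latency_ms(lb) for lb in ann.present()]
                assert all(a < b for a, b in zip(lats, lats[1:]))

    def test_picks_are_extrema_of_matching_polarity(self, annotated_benchmark):
        for st, triples in annotated_benchmark.items():
            rules = (default_abr_rules() if st == ABR else default_amlr_rules())
            for _, ex, ann in triples:
                for lb in ann.present():
                    pool = ex.of_polarity(rules.interval_rules[lb].polarity)
                    assert ann.sample_index(lb) in pool

    def test_annotation_is_deterministic(self, annotated_benchmark):
        for triples in annotated_benchmark.values():
            for w, ex, ann in triples:
                again = annotate(w, ex)
                assert again.waves == ann.waves

    @pytest.mark.parametrize("subtype", [ABR, AMLR])
    def test_clean_recordings_recovered_exactly(self, subtype):
        """Noise-free recordings: every planted component is recovered within
        one sample of its extremum on the display-filtered template."""
        spec = synth.default_benchmark_spec(subtype)
        spec.buffer_noise_sd_uv = 0.0
        recs, _, params = synth.generate_benchmark(
            100, subtype, seed=5, spec=spec, return_params=True
        )
        for rec, p in zip(recs, params):
            w = apply_display_filters(average_buffers(rec))
            ann = annotate(w)
            oracle = component_extrema(p, "default")
            for lb, gi in oracle.items():
                pi = ann.sample_index(lb)
                assert pi is not None and abs(pi - gi) <= 1, (
                    f"{rec.patient_id} {lb}: picked {pi}, expected {gi}"
                )
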