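import numpy as np
import pytest

from aepannot import (
    ABR,
    AMLR,
    WAVE_LABELS,
    annotate_amlr,
    apply_display_filters,
    average_buffers,
    detect_pam,
    find_local_extrema,
    read_recording_xml,
)
from aepannot.annotation import default_rules
from aepannot.synth import (
    Component,
    GenerationError,
    SynthParams,
    default_benchmark_spec,
    generate_benchmark,
    generate_recording,
)


def _abr_params(noise=0.0, seed=0):
    comps = {
        "I": Component(1.5, 0.3, 0.25),
        "II": Component(2.5, 0.25, 0.25),
        "III": Component(3.5, 0.3, 0.25),
        "IV": Component(4.5, 0.25, 0.25),
        "V": Component(5.5, 0.45, 0.25),
    }
    return SynthParams(ABR, comps, buffer_noise_sd_uv=noise, seed=seed)


class TestGenerateRecording:
    def test_noise_free_extrema_exactly_at_gold(self):
        rec = generate_recording(_abr_params(noise=0.0))
        w = average_buffers(rec)
        ex = find_local_extrema(w)
        for lb, gi in rec.gold_waves.items():
            assert gi in ex.peak_indices  # all ABR components are peaks

    def test_same_seed_reproduces_recording(self):
        a = generate_recording(_abr_params(noise=0.1, seed=99))
        b = generate_recording(_abr_params(noise=0.1, seed=99))
        assert np.array_equal(a.buffer_a, b.buffer_a)
        assert np.array_equal(a.buffer_b, b.buffer_b)
        assert a.gold_waves == b.gold_waves
        c = generate_recording(_abr_params(noise=0.1, seed=100))
        assert not np.array_equal(a.buffer_a, c.buffer_a)

    def test_buffer_averaging_halves_noise_variance(self):
        """Monte-Carlo: the two-buffer average tracks the clean template
        better than either single buffer."""
        from aepannot.preprocess import build_time_axis
        from aepannot.synth import SAMPLE_RATE_HZ, _template

        p0 = _abr_params(noise=0.1)
        t = build_time_axis(450, SAMPLE_RATE_HZ[ABR])
        template = _template(p0, t)
        err_avg, err_single = [], []
        for seed in range(100):
            rec = generate_recording(_abr_params(noise=0.1, seed=seed))
            avg = average_buffers(rec).amplitudes
            single = rec.buffer_a * rec.raw_to_microvolt
            err_avg.append(np.sqrt(np.mean((avg - template) ** 2)))
            err_single.append(np.sqrt(np.mean((single - template) ** 2)))
        assert np.mean(err_avg) < np.mean(err_single)
        # the reduction should be close to 1/sqrt(2)
        assert np.mean(err_avg) / np.mean(err_single) == pytest.approx(
            1 / np.sqrt(2), rel=0.1
        )

    def test_microvolt_round_trip_through_preprocess(self):
        p = _abr_params(noise=0.0)
        p.raw_to_microvolt = 0.01
        rec = generate_recording(p)
        w = average_buffers(rec)
        assert np.max(np.abs(w.amplitudes)) == pytest.approx(0.45, abs=0.02)

    def test_merged_components_warn(self):
        comps = {
            "I": Component(1.50, 0.3, 0.25),
            "II": Component(1.55, 0.3, 0.25),  # merges with I
            "III": Component(3.5, 0.3, 0.25),
            "IV": Component(4.5, 0.25, 0.25),
            "V": Component(5.5, 0.45, 0.25),
        }
        with pytest.warns(UserWarning, match="merged"):
            generate_recording(SynthParams(ABR, comps, seed=0))

    def test_latency_outside_window_rejected(self):
        comps = {"I": Component(16.0, 0.3, 0.25)}
        with pytest.raises(GenerationError):
            generate_recording(SynthParams(ABR, comps, seed=0)).validate()


class TestGenerateBenchmark:
    def test_structure_and_round_trip(self, tmp_path):
        recs, gold = generate_benchmark(
            20, ABR, seed=42, out_dir=tmp_path / "bench"
        )
        assert len(recs) == 20
        assert (tmp_path / "bench" / "gold.csv").exists()
        rules = default_rules(ABR)
        for rec in recs:
            assert len(rec.gold_waves) == 5
            back = read_recording_xml(tmp_path / "bench" / f"{rec.patient_id}.xml")
            assert back.equals(rec)
            w = apply_display_filters(average_buffers(back))
            assert w.n_samples == 450
        # gold latencies lie inside the generating core intervals
        t_step = 1000.0 / 30000.0
        for rec in recs:
            for lb, gi in rec.gold_waves.items():
                lo, hi = rules.interval_rules[lb].core_ms
                assert lo - 2 * t_step <= gi * t_step <= hi + 2 * t_step

    def test_gap_rules_respected_by_construction(self):
        recs, gold = generate_benchmark(30, AMLR, seed=1)
        rules = default_rules(AMLR)
        t_step = 1000.0 / 3000.0
        for rec in recs:
            lat = {lb: gi * t_step for lb, gi in rec.gold_waves.items()}
            for g in rules.inter_wave_rules:
                gap = lat[g.to_label] - lat[g.from_label]
                lo, hi = g.allowed_gap_ms
                # template overlap may nudge gold extrema by a sample or two
                assert lo - 3 * t_step <= gap <= hi + 3 * t_step

    def test_zero_count_rejected(self):
        with pytest.raises(GenerationError):
            generate_benchmark(0, ABR, seed=0)

    def test_pam_fixture_triggers_detector(self):
        recs, gold = generate_benchmark(1, AMLR, seed=4, pam_fraction=1.0)
        rec = recs[0]
        w = apply_display_filters(average_buffers(rec))
        ex = find_local_extrema(w)
        ann = annotate_amlr(w, ex)
        assert detect_pam(w, ex, ann).detected

    def test_benchmark_reproducible(self):
        a, _ = generate_benchmark(5, ABR, seed=13)
        b, _ = generate_benchmark(5, ABR, seed=13)
        for ra, rb in zip(a, b):
            assert ra.equals(rb)
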