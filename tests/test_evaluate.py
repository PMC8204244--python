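"""Beat matching, accuracy arithmetic, subensemble SNR, cohort summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgbeat import (
    J_TRUTH_RULE,
    R_REFERENCE_RULE,
    SimConfig,
    accuracy_percent,
    apply_bandpass,
    cohort_summary,
    design_bandpass,
    estimate_snr,
    load_reference_table,
    make_beat_template,
    match_beats,
    simulate_recording,
    snr_for_recording,
    subensemble_average,
)


class TestMatchBeats:
    def test_identity_under_symmetric_rule(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        m = match_beats(t, t, J_TRUTH_RULE)
        assert (m.tp, m.fp, m.undetected) == (4, 0, 0)

    def test_latency_window_rule_hand_example(self):
        # J at 1.2 matches R at 1.0 (latency 0.2); J at 2.6 is 0.6 s after
        # R at 2.0, outside [0.05, 0.45] -> FP, and that R goes undetected
        m = match_beats([1.2, 2.6], [1.0, 2.0], R_REFERENCE_RULE)
        assert (m.tp, m.fp, m.undetected) == (1, 1, 1)
        assert m.pairs == ((1.0, 1.2),)

    def test_empty_detection_list(self):
        m = match_beats([], [1.0, 2.0, 3.0, 4.0, 5.0], R_REFERENCE_RULE)
        assert (m.tp, m.fp, m.undetected) == (0, 0, 5)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            match_beats([2.0, 1.0], [1.0], R_REFERENCE_RULE)

    def test_matching_is_one_to_one(self):
        # two detections cannot claim one reference
        m = match_beats([1.1, 1.3], [1.0], R_REFERENCE_RULE)
        assert (m.tp, m.fp) == (1, 1)

    @settings(deadline=None, max_examples=50)
    @given(
        det=st.lists(st.floats(0, 100), max_size=30),
        ref=st.lists(st.floats(0, 100), max_size=30),
    )
    def test_conservation_invariants(self, det, ref):
        det = np.unique(np.round(det, 3))
        ref = np.unique(np.round(ref, 3))
        m = match_beats(det, ref, R_REFERENCE_RULE)
        assert m.tp + m.undetected == ref.size
        assert m.tp + m.fp == det.size
        assert len(set(r for r, _ in m.pairs)) == m.tp  # one-to-one


class TestAccuracy:
    @pytest.mark.parametrize(
        "tp,ref,expected", [(72, 73, 98.6), (77, 81, 95.1), (0, 50, 0.0), (46, 69, 66.7)]
    )
    def test_percentage_arithmetic(self, tp, ref, expected):
        assert accuracy_percent(tp, ref) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            accuracy_percent(5, 0)


class TestSubensemble:
    def test_identical_beats_average_to_template(self):
        fs = 250.0
        w = make_beat_template(fs=fs)
        x = np.zeros(int(10 * fs))
        beats = np.arange(0.5, 9.5, 1.0)
        for t in beats:
            i = int(round(t * fs)) - len(w) // 2
            x[i: i + len(w)] += w
        avg = subensemble_average(x, fs, beats, (0.0, 10.0))
        assert np.allclose(avg, w, atol=1e-12)

    def test_noise_averages_down_as_sqrt_m(self, rng):
        fs, m = 250.0, 16
        w = make_beat_template(fs=fs)
        sigma = 0.3
        x = np.zeros(int((m + 2) * fs))
        beats = np.arange(1.0, m + 1.0)
        for t in beats:
            i = int(round(t * fs)) - len(w) // 2
            x[i: i + len(w)] += w
        resid_sds = []
        for _ in range(20):
            noisy = x + rng.normal(0, sigma, x.size)
            avg = subensemble_average(noisy, fs, beats, (0.0, m + 2.0))
            resid_sds.append((avg - w).std())
        assert np.mean(resid_sds) == pytest.approx(sigma / math.sqrt(m), rel=0.25)

    def test_single_beat_in_span_rejected(self):
        x = np.zeros(2500)
        with pytest.raises(ValueError, match="at least 2"):
            subensemble_average(x, 250.0, [1.0, 8.0], (0.0, 5.0))


class TestSnr:
    def test_identical_averages_give_infinity(self):
        e = np.sin(np.linspace(0, 3, 100))
        assert math.isinf(estimate_snr(e, e))

    def test_anticorrelated_averages_rejected(self):
        t = np.linspace(-1, 1, 100)
        with pytest.raises(ValueError, match="coherent"):
            estimate_snr(t, -t)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_snr(np.ones(10), np.ones(11))

    def test_known_signal_plus_noise_level(self, rng):
        # E1/E2 = s + independent noise of SD sigma_e: SNR ~ P_s / sigma_e^2
        s = np.sin(np.linspace(0, 6 * np.pi, 400))
        sigma_e = 0.05
        vals = [
            estimate_snr(s + rng.normal(0, sigma_e, s.size),
                         s + rng.normal(0, sigma_e, s.size))
            for _ in range(50)
        ]
        expected = 10 * math.log10(np.mean(s**2) / sigma_e**2)
        assert np.mean(vals) == pytest.approx(expected, abs=1.0)

    def test_snr_decreases_with_simulator_noise(self):
        # doubling the noise SD lowers the subensemble SNR for every seed
        for seed in range(3):
            prev = math.inf
            for sd in (0.1, 0.2, 0.4):
                cfg = SimConfig(duration_s=25.0, mean_hr_bpm=70.0, noise_sd=sd,
                                seed=seed)
                rec, truth = simulate_recording(cfg)
                filt = apply_bandpass(rec, design_bandpass(fs=rec.fs))
                val = snr_for_recording(filt.samples, filt.fs, truth.j_times).snr_db
                assert val < prev
                prev = val


class TestCohort:
    def test_reference_cohort_means(self):
        table = load_reference_table("detection")
        s = cohort_summary(table)
        assert s.accuracy_mean == 91.4
        assert s.accuracy_sd == 9.4
        assert s.snr_mean_db == 31.7

    def test_pooled_accuracy_excluding_outliers(self):
        table = load_reference_table("detection")
        s = cohort_summary(table, exclude=(4, 15, 20))
        assert (s.pooled_tp, s.pooled_reference) == (1136, 1200)
        assert s.pooled_accuracy_percent == pytest.approx(94.67, abs=0.01)

    def test_single_perfect_recording(self):
        import pandas as pd

        df = pd.DataFrame({"participant_id": [1], "total_r_peaks": [10],
                           "true_positives": [10]})
        s = cohort_summary(df)
        assert s.accuracy_mean == 100.0 and s.accuracy_sd == 0.0
        assert s.pooled_accuracy_percent == 100.0

    def test_all_excluded_rejected(self):
        table = load_reference_table("detection")
        with pytest.raises(ValueError, match="excluded"):
            cohort_summary(table, exclude=tuple(range(1, 21)))
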