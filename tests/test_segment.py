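"""Moving-variance artifact segmentation and segment statistics."""

import numpy as np
import pytest

from bcgbeat import (
    Recording,
    SegmentSet,
    VarianceSeries,
    find_clean_segments,
    moving_variance,
    summarize_segments,
)

FS = 250.0


class TestMovingVariance:
    def test_constant_signal_gives_zero_variance(self):
        var = moving_variance(Recording(np.full(2500, 2.0), FS))
        assert np.all(var.values == 0.0)

    @pytest.mark.parametrize("mode", ["sliding", "tiled"])
    def test_iid_noise_matches_sigma_squared(self, mode, rng):
        sigma = 0.7
        rec = Recording(rng.normal(0, sigma, int(60 * FS)), FS)
        var = moving_variance(rec, mode=mode)
        assert var.values.mean() == pytest.approx(sigma**2, rel=0.10)

    def test_burst_windows_dominate(self, rng):
        x = rng.normal(0, 0.1, int(20 * FS))
        x[int(5 * FS): int(10 * FS)] *= 10.0
        var = moving_variance(Recording(x, FS), mode="tiled")
        burst = var.values[5:10].min()
        elsewhere = var.values[np.r_[0:5, 10:20]].max()
        assert burst > 50.0 * elsewhere

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            moving_variance(Recording(np.ones(100), FS), window_s=1.0)

    def test_sliding_matches_direct_computation(self, rng):
        x = rng.normal(size=1000)
        var = moving_variance(Recording(x, FS), window_s=1.0, mode="sliding")
        w = var.window_samples
        direct = np.array([x[i: i + w].var() for i in range(x.size - w + 1)])
        assert np.allclose(var.values, direct, atol=1e-10)


class TestFindCleanSegments:
    def test_constant_variance_keeps_whole_recording(self):
        # degenerate all-clean case: every window equals the mean, and the
        # literal rule (v > v/2) would discard everything
        var = VarianceSeries(np.full(300, 1.3), int(FS), int(FS), FS)
        segs = find_clean_segments(var, 0.5, 5.0)
        assert len(segs) == 1
        assert segs.intervals[0] == (0, 300 * int(FS))

    def test_single_burst_window_splits_recording(self):
        # hand-evaluated: mean = 15.14, threshold = 7.57; only the 100 window
        # exceeds it, so runs [0,3)s and [4,7)s survive a 2 s minimum
        var = VarianceSeries(np.array([1, 1, 1, 100, 1, 1, 1.0]), int(FS), int(FS), FS)
        segs = find_clean_segments(var, 0.5, 2.0)
        assert segs.intervals == ((0, 3 * int(FS)), (4 * int(FS), 7 * int(FS)))

    def test_short_runs_dropped(self):
        v = np.array([1, 100, 1, 1, 1, 1, 1, 1, 100, 1.0])
        var = VarianceSeries(v, int(FS), int(FS), FS)
        segs = find_clean_segments(var, 0.5, 5.0)
        assert segs.intervals == ((2 * int(FS), 8 * int(FS)),)

    def test_threshold_monotonicity(self, rng):
        v = rng.uniform(0.5, 20.0, 120)
        var = VarianceSeries(v, int(FS), int(FS), FS)
        totals = [
            find_clean_segments(var, f, 1.0).total_clean_s
            for f in (0.25, 0.5, 1.0, 2.0)
        ]
        assert totals == sorted(totals)

    def test_recovers_simulated_artifact_schedule(self):
        from bcgbeat import SimConfig, apply_bandpass, design_bandpass, simulate_recording

        sched = ((40.0, 30.0, 8.0), (120.0, 50.0, 6.0), (210.0, 40.0, 10.0))
        cfg = SimConfig(duration_s=300.0, mean_hr_bpm=70.0, artifacts=sched, seed=9)
        rec, truth = simulate_recording(cfg)
        filt = apply_bandpass(rec, design_bandpass(fs=rec.fs))
        var = moving_variance(filt, mode="tiled")
        segs = find_clean_segments(var, n_samples=filt.n)
        truth_clean = 300.0 - sum(b - a for a, b in truth.artifact_intervals)
        assert segs.total_clean_s == pytest.approx(truth_clean, abs=3.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            VarianceSeries(np.array([]), int(FS), int(FS), FS)

    def test_window_bookkeeping_is_conservative(self, rng):
        # kept + discarded = total; intervals disjoint and sorted
        v = rng.uniform(0.5, 30.0, 200)
        var = VarianceSeries(v, int(FS), int(FS), FS)
        segs = find_clean_segments(var, 0.5, 1.0)
        n_kept = int((v <= 0.5 * v.mean()).sum())
        assert n_kept + int((v > 0.5 * v.mean()).sum()) == v.size
        starts = [s for s, _ in segs.intervals]
        assert starts == sorted(starts)
        for (s1, e1), (s2, e2) in zip(segs.intervals, segs.intervals[1:]):
            assert e1 <= s2


class TestSummarize:
    def test_empty_set(self):
        stats = summarize_segments(SegmentSet((), 300 * int(FS), FS, 5.0))
        assert (stats.count, stats.total_clean_s, stats.percent_clean) == (0, 0.0, 0.0)

    def test_percent_clean_arithmetic(self):
        fs = int(FS)
        segs = SegmentSet(((0, 100 * fs), (150 * fs, 200 * fs)), 300 * fs, FS, 5.0)
        stats = summarize_segments(segs)
        assert stats.count == 2
        assert stats.shortest_s == 50.0 and stats.longest_s == 100.0
        assert stats.percent_clean == pytest.approx(50.0)

    @pytest.mark.parametrize(
        "total,expected", [(264.6, 88.2), (177.9, 59.3), (97.1, 32.4), (89.1, 29.7)]
    )
    def test_reference_cohort_percentages(self, total, expected):
        # percent clean recomputed from mean clean duration over 300 s
        assert 100.0 * total / 300.0 == pytest.approx(expected, abs=0.05)
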