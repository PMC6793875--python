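"""HRV feature extraction: closed-form examples, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectlab import hrv, synthetic
from affectlab.hrv import RRSeries


class TestRRSeries:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RRSeries(beat_times=[0.0, 1.0], intervals=[1000.0, 900.0])
        with pytest.raises(ValueError):
            RRSeries.from_intervals([800.0, -5.0])

    def test_window_selects_contained_beats(self):
        rr = RRSeries.from_intervals(np.full(60, 1000.0))
        win = rr.window(10.0, 20.0)
        assert len(win) == 9  # beats at 10..19 s -> 10 beats, 9 intervals
        assert win.beat_times[0] >= 10.0 and win.beat_times[-1] < 20.0


class TestDetectRPeaks:
    def test_clean_60bpm_recovers_every_beat(self):
        rr = RRSeries.from_intervals(np.full(60, 1000.0))
        ecg = synthetic.render_ecg(rr, 256.0)
        det = hrv.detect_r_peaks(ecg, 256.0)
        assert 59 <= len(det.beat_times) <= 61
        truth = np.round(rr.beat_times * 256).astype(int)
        found = np.round(det.beat_times * 256).astype(int)
        for t in truth:
            assert np.min(np.abs(found - t)) <= 1

    def test_flat_signal_raises(self):
        with pytest.raises(hrv.DetectionError):
            hrv.detect_r_peaks(np.zeros(256 * 20), 256.0)

    def test_too_short_raises(self):
        with pytest.raises(hrv.DetectionError):
            hrv.detect_r_peaks(np.sin(np.arange(256 * 5) / 10.0), 256.0)


class TestDetrend:
    def test_linear_drift_removed_mean_kept(self, rng):
        x = np.linspace(800, 900, 300) + 5 * rng.standard_normal(300)
        rr = RRSeries.from_intervals(x)
        det = hrv.detrend_rr(rr, lam=500.0)
        b_raw = np.polyfit(np.arange(300), x, 1)[0]
        b_det = np.polyfit(np.arange(300), det.intervals, 1)[0]
        assert abs(b_det) < 0.05 * abs(b_raw)
        assert det.intervals.mean() == pytest.approx(x.mean(), rel=1e-9)

    def test_constant_series_unchanged(self):
        rr = RRSeries.from_intervals(np.full(50, 850.0))
        det = hrv.detrend_rr(rr, lam=500.0)
        np.testing.assert_allclose(det.intervals, 850.0, atol=1e-6)

    def test_lambda_to_zero_limit_gives_zero_residual(self, rng):
        x = 850 + 30 * rng.standard_normal(100)
        det = hrv.detrend_rr(RRSeries.from_intervals(x), lam=1e-3)
        assert np.var(det.intervals) < 1e-4 * np.var(x)

    def test_nonpositive_lambda_rejected(self):
        rr = RRSeries.from_intervals(np.full(20, 800.0))
        with pytest.raises(ValueError):
            hrv.detrend_rr(rr, lam=0.0)


class TestCorrectEctopics:
    def test_single_long_beat_flagged_and_interpolated(self):
        x = np.full(60, 800.0)
        x[30] = 2000.0
        out = hrv.correct_ectopics(RRSeries.from_intervals(x))
        assert out.corrected_flags.sum() == 1 and out.corrected_flags[30]
        assert 700.0 <= out.intervals[30] <= 900.0

    def test_clean_series_untouched(self, rng):
        x = 800 + 20 * rng.standard_normal(100)
        out = hrv.correct_ectopics(RRSeries.from_intervals(x))
        assert out.corrected_flags.sum() == 0
        np.testing.assert_allclose(out.intervals, x)

    def test_bigeminy_flags_match_local_median_rule(self):
        # alternating short/long pattern against a normal background
        x = np.concatenate([np.full(20, 800.0),
                            np.tile([500.0, 1100.0], 3),
                            np.full(20, 800.0)])
        rr = RRSeries.from_intervals(x)
        # brute-force application of the rule
        expect = np.zeros(len(x), dtype=bool)
        for i in range(len(x)):
            lo, hi = max(0, i - 5), min(len(x), i + 6)
            med = np.median(x[lo:hi])
            expect[i] = abs(x[i] - med) > 0.25 * med
        with pytest.warns(RuntimeWarning) if expect.mean() > 0.2 else np.errstate():
            out = hrv.correct_ectopics(rr)
        np.testing.assert_array_equal(out.corrected_flags, expect)

    def test_majority_corrupt_raises(self):
        x = np.tile([400.0, 1600.0], 20)
        with pytest.raises(RuntimeError):
            hrv.correct_ectopics(RRSeries.from_intervals(x))


class TestTimeDomain:
    @pytest.mark.parametrize("intervals, field, expected", [
        ([800.0, 850.0, 800.0], "rmssd", 50.0),
        ([800.0, 860.0, 800.0, 820.0], "pnn50", 200.0 / 3.0),
        ([800.0] * 20, "std_rr", 0.0),
        ([800.0] * 20, "rmssd", 0.0),
        ([800.0] * 20, "pnn50", 0.0),
    ])
    def test_closed_form_examples(self, intervals, field, expected):
        out = hrv.hrv_time_features(RRSeries.from_intervals(intervals))
        assert out[field] == pytest.approx(expected, abs=1e-9)

    def test_undefined_markers_for_tiny_input(self):
        out = hrv.hrv_time_features(RRSeries.from_intervals([800.0]))
        assert np.isfinite(out["mean_rr"]) and np.isnan(out["std_rr"])

    def test_triangular_index_matches_histogram_oracle(self, rng):
        x = 850 + 60 * rng.standard_normal(500)
        out = hrv.hrv_time_features(RRSeries.from_intervals(x))
        width = 1000.0 / 128.0  # 1/128 s bins
        lo = np.floor(x.min() / width) * width
        nbins = int(round((np.ceil(x.max() / width) * width - lo) / width))
        counts, _ = np.histogram(x, bins=nbins, range=(lo, lo + nbins * width))
        assert out["rr_tri_index"] == pytest.approx(len(x) / counts.max())
        assert out["tinn"] > 0


class TestFrequencyDomain:
    def test_single_lf_sinusoid(self):
        t = np.arange(500)
        x = 900 + 60 * np.sin(2 * np.pi * 0.1 * np.cumsum(np.full(500, 0.9)))
        out = hrv.hrv_freq_features(RRSeries.from_intervals(x))
        assert out["lf_peak"] == pytest.approx(0.10, abs=0.01)
        assert out["hf_pow"] < 0.05 * out["lf_pow"]

    def test_equal_amplitude_lf_hf_ratio_near_one(self):
        dt = 0.9
        t = np.cumsum(np.full(600, dt))
        x = 900 + 40 * np.sin(2 * np.pi * 0.1 * t) + 40 * np.sin(2 * np.pi * 0.3 * t)
        out = hrv.hrv_freq_features(RRSeries.from_intervals(x))
        assert 0.8 <= out["lf_hf"] <= 1.25

    def test_normalized_units_identity(self, rng):
        rr = synthetic.generate_rr_series(900, 50, 2.0, 400, seed=11)
        out = hrv.hrv_freq_features(rr)
        assert out["lf_nu"] + out["hf_nu"] == pytest.approx(100.0, abs=0.1)

    def test_short_span_gives_undefined_markers(self):
        rr = RRSeries.from_intervals(np.full(20, 900.0))
        out = hrv.hrv_freq_features(rr)
        assert np.isnan(out["lf_pow"]) and np.isnan(out["lf_hf"])


class TestPoincare:
    def test_alternating_series_closed_form(self):
        rr = RRSeries.from_intervals([800.0, 900.0] * 100)
        out = hrv.poincare_features(rr)
        assert out["sd1"] == pytest.approx(100.0 / np.sqrt(2), abs=1e-9)
        assert out["sd2"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_series(self):
        out = hrv.poincare_features(RRSeries.from_intervals([800.0] * 10))
        assert out["sd1"] == 0.0 and out["sd2"] == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=400, max_value=1500), min_size=3,
                    max_size=50))
    def test_sd1_rmssd_identity_everywhere(self, intervals):
        rr = RRSeries.from_intervals(intervals)
        sd1 = hrv.poincare_features(rr)["sd1"]
        rmssd = hrv.hrv_time_features(rr)["rmssd"]
        assert sd1 == pytest.approx(rmssd / np.sqrt(2), rel=1e-9, abs=1e-12)


class TestEntropy:
    def test_periodic_series_low_sampen(self):
        rr = RRSeries.from_intervals([800.0, 900.0] * 100)
        out = hrv.entropy_features(rr)
        assert out["sampen"] < 0.1

    def test_noise_more_irregular_than_periodic(self, rng):
        per = hrv.entropy_features(RRSeries.from_intervals([800.0, 900.0] * 250))
        noise = hrv.entropy_features(
            RRSeries.from_intervals(850 + 50 * rng.standard_normal(500)))
        assert per["sampen"] < noise["sampen"]
        assert np.isfinite(noise["apen"])

    def test_constant_series_undefined(self):
        out = hrv.entropy_features(RRSeries.from_intervals([800.0] * 200))
        assert np.isnan(out["apen"]) and np.isnan(out["sampen"])


class TestDFA:
    def test_white_noise_and_random_walk_exponents(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            white = RRSeries.from_intervals(900 + 30 * r.standard_normal(1000))
            walk = RRSeries.from_intervals(
                5000 + 30 * np.cumsum(r.standard_normal(1000)))
            assert 0.4 <= hrv.dfa_features(white)["dfa_a1"] <= 0.65
            assert 1.3 <= hrv.dfa_features(walk)["dfa_a1"] <= 1.7

    def test_constant_series_undefined(self):
        out = hrv.dfa_features(RRSeries.from_intervals([900.0] * 300))
        assert np.isnan(out["dfa_a1"]) and np.isnan(out["dfa_a2"])

    def test_short_series_alpha2_undefined(self, rng):
        rr = RRSeries.from_intervals(900 + 30 * rng.standard_normal(100))
        out = hrv.dfa_features(rr)
        assert np.isfinite(out["dfa_a1"]) and np.isnan(out["dfa_a2"])


class TestCorrelationDimension:
    def test_limit_cycle_low_dimension(self):
        t = np.arange(1000)
        rr = RRSeries.from_intervals(900 + 80 * np.sin(2 * np.pi * 0.08 * t))
        assert 0.8 <= hrv.correlation_dimension(rr) <= 1.5

    def test_white_noise_no_saturation(self, rng):
        rr = RRSeries.from_intervals(900 + 50 * rng.standard_normal(1000))
        assert hrv.correlation_dimension(rr) >= 3.0

    def test_constant_series_undefined(self):
        assert np.isnan(hrv.correlation_dimension(
            RRSeries.from_intervals([900.0] * 300)))


class TestFullVector:
    def test_26_features_finite_or_nan(self, rng):
        rr = synthetic.generate_rr_series(900, 50, 1.5, 300, seed=3)
        out = hrv.hrv_features(rr)
        assert list(out) == hrv.HRV_FEATURE_NAMES
        assert len(out) == 26
        for v in out.values():  # no infs ever; NaN is the undefined marker
            assert np.isnan(v) or np.isfinite(v)

    def test_band_percentages_account_for_everything(self):
        rr = synthetic.generate_rr_series(900, 50, 2.0, 400, seed=5)
        out = hrv.hrv_features(rr)
        total_pct = out["vlf_pct"] + out["lf_pct"] + out["hf_pct"]
        assert total_pct == pytest.approx(100.0, abs=0.1)
        assert all(out[k] >= 0 for k in
                   ("vlf_pow", "lf_pow", "hf_pow", "total_pow"))
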