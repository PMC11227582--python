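"""Processing-chain and detector tests, each against an independent oracle:
a brute-force per-index rolling median, a grid-search exponential fit, a
threshold re-scan of all local maxima, and an empirical-CDF enumeration for
the KS statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striakit.exceptions import DataError
from striakit.photometry import (
    EventTrain,
    PhotometryRecording,
    compare_event_trains,
    detect_events,
    preprocess_trace,
    rolling_median,
    summarize_events,
)
from striakit.simulate import PhotometrySimConfig, simulate_photometry

from conftest import inject_kernels, make_trace
from oracles import (
    oracle_detect,
    oracle_exp_fit,
    oracle_ks_statistic,
    oracle_rolling_median,
)


# ---------------------------------------------------------------------------
# rolling median


class TestRollingMedian:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.7)
        assert np.array_equal(rolling_median(x, 11), x)

    def test_median_rejects_outlier(self):
        out = rolling_median(np.array([1.0, 2.0, 100.0, 2.0, 1.0]), 5)
        assert out[2] == 2.0

    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            w = int(rng.integers(1, 20))
            x = rng.standard_normal(n)
            assert np.array_equal(rolling_median(x, w),
                                  oracle_rolling_median(x, w))

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            rolling_median(np.array([]), 5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
           st.integers(1, 15))
    def test_oracle_equality_property(self, xs, w):
        x = np.asarray(xs)
        assert np.array_equal(rolling_median(x, w),
                              oracle_rolling_median(x, w))


# ---------------------------------------------------------------------------
# preprocessing


class TestPreprocess:
    def test_identical_channels_have_zero_variance_after_subtraction(self, rng):
        t = np.arange(3000) / 100.0
        x = 50.0 + rng.standard_normal(3000)
        rec = PhotometryRecording(time_s=t, f_signal=x, f_control=x.copy(),
                                  rate_hz=100.0)
        with pytest.raises(DataError, match="zero variance"):
            preprocess_trace(rec, target_rate_hz=100.0)

    def test_constant_channels_rejected(self):
        t = np.arange(1000) / 100.0
        rec = PhotometryRecording(time_s=t, f_signal=np.full(1000, 20.0),
                                  f_control=np.full(1000, 20.0), rate_hz=100.0)
        with pytest.raises(DataError):
            preprocess_trace(rec, target_rate_hz=100.0)

    def test_detrend_matches_gridsearch_fit(self):
        # pure bleach, no events/noise: the fitted exponential must track the
        # true decay so closely that the residual trend is flat
        cfg = PhotometrySimConfig(duration_s=600.0, rate_hz=100.0,
                                  bleach_amp=40.0, bleach_tau_s=300.0,
                                  event_rate_per_min=0.0, artifact_sd=0.0,
                                  noise_sd=0.01, seed=1)
        rec, _ = simulate_photometry(cfg)
        x = rec.f_signal - rec.autofluorescence_signal
        t = rec.time_s
        a_o, tau_o, c_o = oracle_exp_fit(t, x)
        resid = x - (a_o * np.exp(-t / tau_o) + c_o)
        slope = np.polyfit(t, resid, 1)[0]
        bleach_slope0 = cfg.bleach_amp / cfg.bleach_tau_s
        assert abs(slope) < 0.01 * bleach_slope0
        # the package's own fit must agree with the grid-search oracle
        processed = preprocess_trace(rec, target_rate_hz=100.0)
        fit_step = next(s for s in processed.provenance
                        if s["step"] == "detrend" and s["channel"] == "signal")
        assert fit_step["kind"] == "exponential"
        assert fit_step["tau_s"] == pytest.approx(tau_o, rel=0.05)
        assert fit_step["a"] == pytest.approx(a_o, rel=0.05)

    def test_downsampling_reduces_rate_and_length(self):
        cfg = PhotometrySimConfig(duration_s=60.0, rate_hz=600.0, seed=0)
        rec, _ = simulate_photometry(cfg)
        p = preprocess_trace(rec, target_rate_hz=120.0)
        assert p.rate_hz == pytest.approx(120.0)
        assert len(p.z) == 60 * 120

    def test_z_is_standardized(self):
        cfg = PhotometrySimConfig(duration_s=120.0, rate_hz=200.0, seed=6)
        rec, _ = simulate_photometry(cfg)
        p = preprocess_trace(rec)
        assert np.mean(p.z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(p.z) == pytest.approx(1.0, rel=1e-10)

    def test_target_rate_above_recording_rate_rejected(self):
        cfg = PhotometrySimConfig(duration_s=10.0, rate_hz=100.0, seed=0)
        rec, _ = simulate_photometry(cfg)
        with pytest.raises(DataError):
            preprocess_trace(rec, target_rate_hz=500.0)


# ---------------------------------------------------------------------------
# event detection


class TestDetectEvents:
    def test_flat_trace_yields_no_events(self):
        train = detect_events(make_trace(np.zeros(2400)))
        assert len(train) == 0

    def test_inserted_kernels_recovered_and_match_threshold_oracle(self, rng):
        rate = 20.0
        z = rng.standard_normal(int(400 * rate))
        times = [100.0, 200.0, 300.0]
        z = inject_kernels(z, rate, times, amp=10.0)
        train = detect_events(make_trace(z, rate))
        # each inserted event recovered near its onset
        for t0 in times:
            assert np.any(np.abs(train.peak_times_s - t0) < 2.0)
        # full agreement with the independent threshold re-scan
        oracle_idx = oracle_detect(z, rate)
        got_idx = np.round(train.peak_times_s * rate).astype(int)
        assert np.array_equal(np.sort(got_idx), np.sort(oracle_idx))

    def test_min_separation_keeps_larger_peak(self):
        z = np.zeros(1200)
        z[600], z[620] = 8.0, 9.0  # 0.17 s apart at 120 Hz
        train = detect_events(make_trace(z), min_sep_s=0.5)
        assert len(train) == 1
        assert train.peak_times_s[0] == pytest.approx(620 / 120.0)

    def test_min_separation_tie_keeps_earlier_peak(self):
        z = np.zeros(1200)
        z[600] = z[620] = 9.0
        train = detect_events(make_trace(z), min_sep_s=0.5)
        assert len(train) == 1
        assert train.peak_times_s[0] == pytest.approx(600 / 120.0)

    def test_plateau_resolved_to_first_sample(self):
        z = np.zeros(1200)
        z[600:605] = 7.0
        train = detect_events(make_trace(z))
        assert len(train) == 1
        assert train.peak_times_s[0] == pytest.approx(600 / 120.0)

    def test_amplitudes_reported_relative_to_filtered_median(self, rng):
        rate = 20.0
        z = 0.1 * rng.standard_normal(int(200 * rate))
        z = inject_kernels(z, rate, [100.0], amp=10.0)
        train = detect_events(make_trace(z, rate))
        big = train.peak_amplitudes.max()
        assert big == pytest.approx(10.0 - train.filtered_median, abs=0.5)

    def test_affine_invariance_of_event_times(self):
        cfg = PhotometrySimConfig(duration_s=120.0, rate_hz=200.0,
                                  event_rate_per_min=10.0, seed=12)
        rec, _ = simulate_photometry(cfg)
        a, b = 3.5, 40.0
        rec2 = PhotometryRecording(
            time_s=rec.time_s,
            f_signal=a * rec.f_signal + b,
            f_control=a * rec.f_control + b,
            rate_hz=rec.rate_hz,
            autofluorescence_signal=a * rec.autofluorescence_signal + b,
            autofluorescence_control=a * rec.autofluorescence_control + b,
        )
        t1 = detect_events(preprocess_trace(rec))
        t2 = detect_events(preprocess_trace(rec2))
        assert np.allclose(t1.peak_times_s, t2.peak_times_s)

    def test_invalid_parameters_rejected(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(DataError):
            detect_events(tr, filter_k=0)
        with pytest.raises(DataError):
            detect_events(tr, peak_mad="other")

# ---------------------------------------------------------------------------
# summaries and comparisons


class TestSummaries:
    def test_frequency_per_minute(self):
        train = EventTrain(peak_times_s=np.linspace(10, 1100, 10),
                           peak_amplitudes=np.ones(10), duration_s=1200.0)
        assert summarize_events(train).frequency_per_min == pytest.approx(0.5)

    def test_no_events(self):
        train = EventTrain(peak_times_s=np.array([]),
                           peak_amplitudes=np.array([]), duration_s=600.0)
        s = summarize_events(train)
        assert s.frequency_per_min == 0.0
        assert len(s.ieis_s) == 0

    def test_ieis_are_successive_differences(self):
        train = EventTrain(peak_times_s=np.array([0.0, 60.0, 120.0]),
                           peak_amplitudes=np.ones(3), duration_s=180.0)
        assert np.array_equal(summarize_events(train).ieis_s, [60.0, 60.0])


class TestKSComparison:
    def test_identical_samples_give_zero(self):
        d, p = compare_event_trains([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_give_one(self):
        d, _ = compare_event_trains([1, 2, 3], [10, 20, 30])
        assert d == 1.0

    def test_matches_enumeration_oracle(self, rng):
        a, b = [1.0, 2.0], [1.5, 2.5]
        d, _ = compare_event_trains(a, b)
        assert d == pytest.approx(oracle_ks_statistic(np.array(a),
                                                      np.array(b)))
        assert d == pytest.approx(0.5)
        for _ in range(20):
            x = rng.standard_normal(int(rng.integers(2, 12)))
            y = rng.standard_normal(int(rng.integers(2, 12))) + 0.5
            d, _ = compare_event_trains(x, y)
            assert d == pytest.approx(oracle_ks_statistic(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            compare_event_trains([], [1.0])
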