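import numpy as np
import pytest

from conftest import clean_config
from saccadekf.preprocessing import (CalibrationModel, TrialRecord,
                                     apply_calibration, detrend_piecewise,
                                     estimate_measurement_variance,
                                     fit_calibration, peak_average,
                                     remove_outliers_iqr)
from saccadekf.simulate import generate_session, generate_trial
from saccadekf.timeseries import TimeSeries


def make_trial(values, fs=250.0, markers=None, target="C"):
    markers = markers if markers is not None else []
    return TrialRecord(eog=TimeSeries(values, fs), markers=markers, target=target)


def step_trial(step_uv, drift_rate=0.0, fs=250.0):
    """Baseline (1 s) → instantaneous step (1 s) → back (0.5 s), plus drift."""
    n1, n2, n3 = 250, 250, 125
    x = np.concatenate([np.zeros(n1), np.full(n2, step_uv), np.zeros(n3)])
    t = np.arange(x.size) / fs
    x = x + drift_rate * t
    markers = [("start", 0.0), ("cue", 0.9), ("ping", 1.9),
               ("end", (x.size - 1) / fs)]
    return make_trial(x, fs, markers)


class TestDetrend:
    def test_linear_ramp_without_markers_removed_exactly(self):
        t = np.arange(100) / 250.0
        trial = make_trial(5.0 + 3.0 * t)
        out = detrend_piecewise(trial, order=1)
        assert np.allclose(out.eog.values, 0.0, atol=1e-9)

    def test_constant_segment_zeroed(self):
        out = detrend_piecewise(make_trial(np.full(80, 7.0)), order=2)
        assert np.allclose(out.eog.values, 0.0, atol=1e-9)

    def test_step_amplitude_survives_drift_removal(self):
        """0.5 µV/s drift on a 176 µV step: amplitude recovered within 1%."""
        clean = step_trial(176.0)
        drifted = step_trial(176.0, drift_rate=0.5)
        out = detrend_piecewise(drifted, order=1)
        step_est = np.median(out.eog.values[260:490]) - np.median(out.eog.values[:220])
        assert abs(step_est - 176.0) / 176.0 < 0.01
        # and the clean trial passes through unchanged
        out_clean = detrend_piecewise(clean, order=1)
        assert np.allclose(out_clean.eog.values, clean.eog.values, atol=1e-9)

    def test_baseline_normalized_to_zero(self):
        trial = step_trial(176.0, drift_rate=0.5)
        out = detrend_piecewise(trial, order=1)
        assert abs(np.median(out.eog.values[:220])) < 0.5

    def test_too_short_segment_reported(self):
        with pytest.raises(ValueError, match="detrend"):
            detrend_piecewise(make_trial(np.arange(4.0)), order=3)

    def test_segment_mean_near_zero_after_detrend(self, rng):
        trial = make_trial(rng.standard_normal(300) + 12.0)
        out = detrend_piecewise(trial, order=1)
        assert abs(out.eog.values.mean()) < 1e-9


class TestPeakAverage:
    def test_single_plateau_peak(self):
        x = np.concatenate([np.zeros(20), np.full(10, 10.0), np.zeros(20)])
        val, n = peak_average(TimeSeries(x, 250.0), threshold=0.8)
        assert val == 10.0
        assert n == 1

    def test_mean_of_qualifying_peaks(self):
        x = np.zeros(100)
        for i, pk in zip([20, 50, 80], [9.8, 10.1, 10.0]):
            x[i] = pk
        val, n = peak_average(TimeSeries(x, 250.0), threshold=0.8)
        assert n == 3
        assert np.isclose(val, (9.8 + 10.1 + 10.0) / 3)
        assert np.isclose(val, 9.9667, atol=5e-5)

    def test_degenerate_threshold_keeps_global_max_only(self):
        x = np.zeros(100)
        x[[20, 50, 80]] = [9.0, 12.0, 10.0]
        val, n = peak_average(TimeSeries(x, 250.0), threshold=1.0)
        assert (val, n) == (12.0, 1)

    def test_no_qualifying_peaks_is_an_error(self):
        with pytest.raises(ValueError):
            peak_average(TimeSeries(np.linspace(0, 1, 50), 250.0), threshold=0.8)


class TestCalibration:
    def test_zero_noise_recovers_planted_slope_exactly(self):
        cfg = clean_config(K_true=0.25, seed=0)  # 0.25 units per degree
        cal, _ = generate_session(5, 0, cfg)
        model = fit_calibration([t.to_trial_record() for t in cal])
        assert abs(model.K - 0.25) < 1e-12
        assert abs(model.intercept) < 1e-9

    def test_symmetric_targets_give_zero_intercept(self):
        cfg = clean_config(seed=1)
        cal, _ = generate_session(2, 0, cfg)
        model = fit_calibration([t.to_trial_record() for t in cal])
        assert abs(model.intercept) < 1e-9

    def test_two_percent_noise_recovers_slope_within_two_percent(self):
        K_true = 0.47
        ests = []
        for seed in range(50):
            cfg = clean_config(K_true=K_true, seed=seed)
            rng = np.random.default_rng(seed)
            trials = []
            for tgt in "ABCD":
                tr = generate_trial(tgt, cfg, rng).to_trial_record("clean")
                sigma = 0.02 * np.abs(tr.eog.values).max()
                noisy = tr.eog.values + rng.normal(0, sigma, len(tr.eog))
                trials.append(TrialRecord(eog=tr.eog.with_values(noisy),
                                          markers=tr.markers, target=tr.target))
            ests.append(fit_calibration(trials).K)
        assert abs(np.mean(ests) - K_true) / K_true < 0.02

    def test_single_angle_design_rejected(self):
        cfg = clean_config(seed=0)
        rng = np.random.default_rng(0)
        trials = [generate_trial("C", cfg, rng).to_trial_record() for _ in range(3)]
        with pytest.raises(ValueError):
            fit_calibration(trials)

    def test_scale_equivariance(self):
        cfg = clean_config(seed=2)
        cal, _ = generate_session(2, 0, cfg)
        trials = [t.to_trial_record() for t in cal]
        k1 = fit_calibration(trials).K
        scaled = [TrialRecord(eog=t.eog.with_values(3.0 * t.eog.values),
                              markers=t.markers, target=t.target) for t in trials]
        assert np.isclose(fit_calibration(scaled).K, 3.0 * k1, rtol=1e-12)


class TestApplyCalibration:
    def test_identity_map(self):
        sig = TimeSeries([1.0, 2.0, 3.0], 250.0)
        out = apply_calibration(sig, CalibrationModel(K=1.0, intercept=0.0))
        assert np.allclose(out.values, sig.values)
        assert out.unit == "degree"

    def test_slope_and_intercept_arithmetic(self):
        cal = CalibrationModel(K=250.0, intercept=0.0)  # 0.25 mV per degree
        out = apply_calibration(TimeSeries([2750.0], 250.0), cal)
        assert np.isclose(out.values[0], 11.0)

    def test_round_trip_is_identity(self, rng):
        cal = CalibrationModel(K=16.0, intercept=-3.2)
        uv = rng.uniform(-400, 400, 100)
        back = cal.degrees_to_microvolts(cal.microvolts_to_degrees(uv))
        assert np.allclose(back, uv, atol=1e-12)


class TestIqrOutliers:
    def test_toy_example_exact(self):
        kept, frac = remove_outliers_iqr([1, 2, 3, 4, 100])
        assert kept.tolist() == [1, 2, 3, 4]
        assert np.isclose(frac, 0.2)

    def test_identical_values_all_kept(self):
        kept, frac = remove_outliers_iqr([5.0] * 10)
        assert len(kept) == 10 and frac == 0.0

    def test_gaussian_tail_fraction(self, rng):
        v = rng.standard_normal(10_000)
        _, frac = remove_outliers_iqr(v)
        assert abs(frac - 0.007) < 0.003

    def test_idempotent_on_own_output(self, rng):
        v = np.concatenate([rng.standard_normal(200), [50.0, -60.0]])
        kept, _ = remove_outliers_iqr(v)
        kept2, frac2 = remove_outliers_iqr(kept)
        assert np.array_equal(np.sort(kept), np.sort(kept2))
        assert frac2 == 0.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            remove_outliers_iqr([1.0, 2.0, 3.0])


def test_measurement_variance_estimate_tracks_noise_level():
    sds = []
    for seed in range(10):
        cfg = clean_config(seed=seed, noise_sigma=20.0, drift_amp_uv=30.0)
        rng = np.random.default_rng(seed)
        trials = [generate_trial(t, cfg, rng).to_trial_record() for t in "AC"]
        sds.append(np.sqrt(estimate_measurement_variance(trials)))
    assert abs(np.mean(sds) - 20.0) / 20.0 < 0.15
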