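import numpy as np
import pytest
from scipy.linalg import solve_discrete_are

from conftest import reference_kalman, riccati_fixed_point
from saccadekf.kalman import (KalmanState, initial_state, kf_filter_signal,
                              kf_predict, kf_update, steady_state_gain)
from saccadekf.models import build_bm, build_cam, build_cvm, build_lr, build_model
from saccadekf.timeseries import TimeSeries


def _state(x, P):
    x = np.atleast_1d(np.asarray(x, float))
    return KalmanState(x, np.atleast_2d(np.asarray(P, float)), np.zeros(x.size))


class TestPredict:
    def test_bm_identity_transition(self):
        m = build_bm(q=0.01, r=1.0)
        out = kf_predict(_state(5.0, 1.0), m)
        assert np.isclose(out.x_hat[0], 5.0)
        assert np.isclose(out.P[0, 0], 1.01)

    def test_cvm_hand_arithmetic(self):
        m = build_cvm(1.0, q=0.0, r=1.0)
        out = kf_predict(_state([0.0, 1.0], np.eye(2)), m)
        assert np.allclose(out.x_hat, [1.0, 1.0])
        assert np.allclose(out.P, [[2.0, 1.0], [1.0, 1.0]])

    def test_certainty_preserved_without_noise(self):
        m = build_cvm(0.004, q=0.0, r=1.0)
        out = kf_predict(_state([2.0, 3.0], np.zeros((2, 2))), m)
        assert np.allclose(out.P, 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kf_predict(_state([1.0, 2.0], np.eye(2)), build_bm(0.1, 1.0))


class TestUpdate:
    def test_scalar_arithmetic(self):
        m = build_bm(q=0.0, r=1.0)
        out = kf_update(_state(0.0, 1.0), m, z=2.0)
        assert np.isclose(out.K_gain[0], 0.5)
        assert np.isclose(out.x_hat[0], 1.0)
        assert np.isclose(out.P[0, 0], 0.5)

    def test_huge_measurement_noise_ignores_measurement(self):
        m = build_bm(q=0.0, r=1e15)
        out = kf_update(_state(3.0, 1.0), m, z=-100.0)
        assert np.isclose(out.x_hat[0], 3.0, atol=1e-10)
        assert np.allclose(out.K_gain, 0.0, atol=1e-12)

    def test_tiny_measurement_noise_returns_measurement(self):
        m = build_cvm(0.004, q=0.0, r=1e-15)
        out = kf_update(_state([0.0, 0.0], 1e3 * np.eye(2)), m, z=7.5)
        assert np.isclose((m.H @ out.x_hat).item(), 7.5, atol=1e-9)

    def test_joseph_form_agrees_with_standard_form(self):
        m = build_cvm(0.004, q=0.5, r=2.0)
        s = _state([1.0, -2.0], [[2.0, 0.3], [0.3, 1.0]])
        a = kf_update(s, m, z=0.7, joseph=False)
        b = kf_update(s, m, z=0.7, joseph=True)
        assert np.allclose(a.x_hat, b.x_hat, atol=1e-12)
        assert np.allclose(a.P, b.P, atol=1e-10)


class TestFilterSignal:
    def test_constant_input_converges_to_constant(self):
        sig = TimeSeries(np.full(300, 3.0), 250.0)
        for name in ["bm", "cvm", "cam"]:
            m = build_model(name, sig.dt, 0.0, 1.0)
            filt, _ = kf_filter_signal(sig, m)
            assert abs(filt.values[-1] - 3.0) < 1e-9
            # monotone approach in the tail
            err = np.abs(filt.values[-50:] - 3.0)
            assert np.all(np.diff(err) <= 1e-12)

    def test_cvm_tracks_noiseless_ramp(self):
        fs = 250.0
        t = np.arange(500) / fs
        sig = TimeSeries(5.0 + 40.0 * t, fs)
        m = build_cvm(1 / fs, q=0.0, r=1.0)
        init = initial_state(m, sig.values[0])
        init.P = 1e12 * m.R * np.eye(2)  # fully diffuse start
        filt, _ = kf_filter_signal(sig, m, init=init)
        # after burn-in the model class contains the ramp: error -> 0
        assert np.max(np.abs(filt.values[-100:] - sig.values[-100:])) < 1e-6

    def test_bm_five_step_hand_unrolled(self):
        z = [1.0, 2.0, 0.5, -1.0, 3.0]
        q, r = 0.01, 1.0
        m = build_bm(q, r)
        sig = TimeSeries(z, 250.0)
        filt, _ = kf_filter_signal(sig, m)
        # hand recursion with the same diffuse start
        x, P = z[0], 1e3 * r
        expected = []
        for zk in z:
            P = P + q
            K = P / (P + r)
            x = x + K * (zk - x)
            P = (1 - K) * P
            expected.append(x)
        assert np.allclose(filt.values, expected, atol=1e-12)

    @pytest.mark.parametrize("name,kw", [
        ("bm", {}), ("cvm", {}), ("cam", {}),
        ("lr", {"lr_constants": (50.0, 80.0, 30.0, 10.0)}),
    ])
    def test_matches_reference_implementation(self, name, kw, rng):
        """Filtered output equals an independent textbook KF to 1e-9."""
        fs = 250.0
        z = rng.standard_normal(100).cumsum() + 5.0
        sig = TimeSeries(z, fs)
        m = build_model(name, 1 / fs, 0.8, 2.5, **kw)
        init = initial_state(m, z[0])
        filt, final = kf_filter_signal(sig, m)
        ref, ref_gain, _ = reference_kalman(z, m.A, m.H, m.Q, m.R,
                                            init.x_hat, init.P)
        assert np.allclose(filt.values, ref, atol=1e-9)
        assert np.allclose(final.K_gain, ref_gain, atol=1e-9)

    def test_slow_and_fast_paths_agree(self, rng):
        sig = TimeSeries(rng.standard_normal(50), 250.0)
        m = build_cvm(0.004, 0.5, 1.0)
        fast, _ = kf_filter_signal(sig, m)
        slow, states = kf_filter_signal(sig, m, return_states=True)
        assert np.allclose(fast.values, slow.values, atol=1e-12)
        assert len(states) == 50

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kf_filter_signal(TimeSeries([], 250.0), build_bm(0.1, 1.0))

    def test_nan_sample_rejected_with_index(self):
        vals = np.ones(20)
        vals[7] = np.nan
        with pytest.raises(ValueError, match="7"):
            kf_filter_signal(TimeSeries(vals, 250.0), build_bm(0.1, 1.0))


class TestSteadyState:
    def test_bm_closed_form_dare_root(self):
        q, r = 0.5, 2.0
        # scalar predicted-covariance DARE: p^2 - q p - q r = 0
        p = (q + np.sqrt(q * q + 4 * q * r)) / 2
        expected = p / (p + r)
        g = steady_state_gain(build_bm(q, r))
        assert np.isclose(g[0], expected, atol=1e-10)

    def test_bm_zero_process_noise_gain_decays(self):
        m = build_bm(q=0.0, r=1.0)
        sig = TimeSeries(np.ones(3000), 250.0)
        _, final = kf_filter_signal(sig, m)
        assert final.K_gain[0] < 1e-3

    @pytest.mark.parametrize("name", ["cvm", "cam"])
    def test_matches_iterated_riccati_and_scipy_dare(self, name):
        m = build_model(name, 0.004, 0.5, 10.0, q_structure="diagonal")
        g = steady_state_gain(m)
        g_ref = riccati_fixed_point(m.A, m.H, m.Q, m.R)
        assert np.allclose(g, g_ref, atol=1e-8)
        P = solve_discrete_are(m.A.T, m.H.T, m.Q, np.array([[m.R]]))
        g_dare = (P @ m.H.ravel()) / ((m.H @ P @ m.H.T).item() + m.R)
        assert np.allclose(g, g_dare, atol=1e-8)

    def test_running_filter_gain_converges_to_fixed_point(self):
        m = build_cvm(0.004, q=0.5, r=10.0, q_structure="diagonal")
        sig = TimeSeries(np.zeros(2000), 250.0)
        _, final = kf_filter_signal(sig, m)
        assert np.allclose(final.K_gain, steady_state_gain(m), atol=1e-6)


class TestInvariants:
    def test_covariance_stays_symmetric_psd(self, rng):
        m = build_cam(0.004, q=0.7, r=1.3)
        state = initial_state(m, 0.0)
        for _ in range(200):
            state = kf_predict(state, m)
            state = kf_update(state, m, rng.standard_normal())
            assert np.allclose(state.P, state.P.T)
            assert np.linalg.eigvalsh(state.P).min() >= -1e-9

    def test_innovations_are_white_on_model_generated_data(self, rng):
        """Normalized innovations ~ N(0,1) when data truly follow the model."""
        q, r, n = 0.3, 1.5, 10_000
        m = build_bm(q, r)
        x = np.cumsum(rng.normal(0, np.sqrt(q), n))
        z = x + rng.normal(0, np.sqrt(r), n)
        state = KalmanState(np.array([z[0]]), np.array([[r]]), np.zeros(1))
        innov = []
        for zk in z[1:]:
            state = kf_predict(state, m)
            s = (m.H @ state.P @ m.H.T).item() + m.R
            innov.append((zk - (m.H @ state.x_hat).item()) / np.sqrt(s))
            state = kf_update(state, m, zk)
        innov = np.array(innov[100:])
        assert abs(innov.mean()) < 0.05
        assert abs(innov.var() - 1.0) < 0.06

    def test_output_depends_only_on_q_over_r_ratio(self, rng):
        z = rng.standard_normal(200).cumsum()
        sig = TimeSeries(z, 250.0)
        a, _ = kf_filter_signal(sig, build_cvm(0.004, q=0.5, r=2.0))
        b, _ = kf_filter_signal(sig, build_cvm(0.004, q=50.0, r=200.0))
        assert np.allclose(a.values, b.values, atol=1e-9)
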