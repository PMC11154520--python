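"""Kalman filter recursion fusing measured EOG samples with a model prediction.

The filter runs the classic predict/correct scheme against one of the
state-space models in :mod:`saccadekf.models`:

    predict:  x⁻ = A x̂,            P⁻ = A P Aᵀ + Q
    correct:  K  = P⁻ Hᵀ (H P⁻ Hᵀ + R)⁻¹
              x̂  = x⁻ + K (z − H x⁻)
              P  = (I − K H) P⁻          (Joseph form optional)

The measurement is the scalar raw EOG sample; the filtered output is the
potential component H·x̂ after each correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import StateSpaceModel
from .timeseries import TimeSeries

#: Diffuse-start scale: P0 = DIFFUSE_P_SCALE · R · I.
DIFFUSE_P_SCALE = 1e3


@dataclass
class KalmanState:
    """Filter state after a predict or update step.

    ``x_hat`` is the state estimate (length n), ``P`` its covariance,
    ``K_gain`` the most recent Kalman gain (zeros before the first update),
    ``step_index`` the number of measurements absorbed.
    """

    x_hat: np.ndarray
    P: np.ndarray
    K_gain: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        self.x_hat = np.asarray(self.x_hat, dtype=float).ravel()
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.K_gain = np.asarray(self.K_gain, dtype=float).ravel()
        n = self.x_hat.size
        if self.P.shape != (n, n):
            raise ValueError(f"P must be {n}x{n}, got {self.P.shape}")
        if self.K_gain.size != n:
            raise ValueError("K_gain dimension mismatch")


def initial_state(model: StateSpaceModel, first_sample: float) -> KalmanState:
    """Diffuse start: x̂₀ = [first sample, 0, …], P₀ = (10³·R)·I.

    The large P₀ makes the first correction lock onto the data regardless of
    the zero guesses for the derivative states.
    """
    n = model.n
    x0 = np.zeros(n)
    x0[0] = first_sample
    P0 = DIFFUSE_P_SCALE * model.R * np.eye(n)
    return KalmanState(x0, P0, np.zeros(n), 0)


def _check_dims(state: KalmanState, model: StateSpaceModel) -> None:
    if state.x_hat.size != model.n:
        raise ValueError(
            f"state dimension {state.x_hat.size} does not match model {model.name} (n={model.n})"
        )


def kf_predict(state: KalmanState, model: StateSpaceModel) -> KalmanState:
    """Time update: propagate the estimate through the process model."""
    _check_dims(state, model)
    A, Q = model.A, model.Q
    x_pred = A @ state.x_hat
    P_pred = A @ state.P @ A.T + Q
    P_pred = (P_pred + P_pred.T) / 2.0  # keep symmetric
    return KalmanState(x_pred, P_pred, state.K_gain, state.step_index)


def kf_update(state: KalmanState, model: StateSpaceModel, z: float,
              joseph: bool = False) -> KalmanState:
    """Measurement update: blend the prediction with one EOG sample ``z``."""
    _check_dims(state, model)
    H = model.H
    h = H.ravel()
    s = float(h @ state.P @ h) + model.R  # innovation variance, scalar
    if s <= 0:
        raise FloatingPointError(f"innovation variance non-positive ({s})")
    K = (state.P @ h) / s
    innov = float(z) - float(h @ state.x_hat)
    x_new = state.x_hat + K * innov
    I = np.eye(model.n)
    IKH = I - np.outer(K, h)
    if joseph:
        P_new = IKH @ state.P @ IKH.T + model.R * np.outer(K, K)
    else:
        P_new = IKH @ state.P
    P_new = (P_new + P_new.T) / 2.0
    return KalmanState(x_new, P_new, K, state.step_index + 1)


def kf_filter_signal(raw: TimeSeries, model: StateSpaceModel,
                     init: KalmanState | None = None,
                     joseph: bool = False,
                     return_states: bool = False):
    """Run one predict+update per sample over a whole signal.

    Parameters
    ----------
    raw : TimeSeries
        Measured signal; must be non-empty and finite.
    model : StateSpaceModel
        The state estimator supplying predictions.
    init : KalmanState, optional
        Starting state; defaults to the diffuse start of :func:`initial_state`.
    joseph : bool
        Use the Joseph-form covariance update (numerically safer; default is
        the plain (I−KH)P⁻ form).
    return_states : bool
        Also return the per-sample post-update :class:`KalmanState` list.

    Returns
    -------
    filtered : TimeSeries
        H·x̂ after each correction; same length, fs and unit as ``raw``.
    states : list of KalmanState, only if ``return_states``.
    """
    if len(raw) == 0:
        raise ValueError("cannot filter an empty signal")
    raw.require_finite()
    state = init if init is not None else initial_state(model, raw.values[0])
    _check_dims(state, model)
    h = model.H.ravel()
    if return_states:
        out = np.empty(len(raw))
        states: list[KalmanState] = []
        for i, z in enumerate(raw.values):
            state = kf_predict(state, model)
            state = kf_update(state, model, z, joseph=joseph)
            out[i] = h @ state.x_hat
            states.append(state)
        return raw.with_values(out), states

    # fast path: same arithmetic without per-step dataclass construction
    A, Q, R, n = model.A, model.Q, model.R, model.n
    I = np.eye(n)
    x = state.x_hat.copy()
    P = state.P.copy()
    K = state.K_gain.copy()
    step = state.step_index
    out = np.empty(len(raw))
    for i, z in enumerate(raw.values):
        x = A @ x
        P = A @ P @ A.T + Q
        s = float(h @ P @ h) + R
        if s <= 0:
            raise FloatingPointError(f"innovation variance non-positive ({s})")
        K = (P @ h) / s
        x = x + K * (float(z) - float(h @ x))
        IKH = I - np.outer(K, h)
        P = IKH @ P @ IKH.T + R * np.outer(K, K) if joseph else IKH @ P
        P = (P + P.T) / 2.0
        out[i] = h @ x
    final = KalmanState(x, P, K, step + len(raw))
    return raw.with_values(out), final


def steady_state_gain(model: StateSpaceModel, tol: float = 1e-12,
                      max_iter: int = 100_000) -> np.ndarray:
    """Steady-state Kalman gain from the Riccati fixed point.

    Iterates the discrete Riccati recursion on the predicted covariance
    until convergence and returns the corresponding gain vector. The running
    filter's per-step gain converges to this value for any PSD start.
    """
    A, H, Q, R = model.A, model.H, model.Q, model.R
    h = H.ravel()
    P = Q + np.eye(model.n)  # any PSD start
    for _ in range(max_iter):
        s = float(h @ P @ h) + R
        K = (P @ h) / s
        P_post = (np.eye(model.n) - np.outer(K, h)) @ P
        P_next = A @ P_post @ A.T + Q
        P_next = (P_next + P_next.T) / 2.0
        if np.max(np.abs(P_next - P)) < tol * max(1.0, np.max(np.abs(P))):
            s = float(h @ P_next @ h) + R
            return (P_next @ h) / s
        P = P_next
    raise FloatingPointError(
        f"Riccati iteration did not converge within {max_iter} iterations"
    )
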