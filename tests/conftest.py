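import numpy as np
import pytest

from saccadekf.simulate import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def clean_config(**overrides) -> GeneratorConfig:
    """Generator config with every stochastic component disabled."""
    base = dict(noise_snr_db=None, noise_sigma=0.0, drift_amp_uv=0.0,
                line_amp_60hz=0.0, blink_rate=0.0, gain_sd=0.0,
                fixation_jitter_s=0.0, el_noise_deg=0.0, latency_sd=0.0)
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture
def clean_cfg():
    return clean_config()


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately separate from the package code paths)
# ---------------------------------------------------------------------------

def reference_kalman(z, A, H, Q, R, x0, P0):
    """Textbook Kalman filter written in plain matrix form with explicit
    column vectors and a matrix inverse — an independent re-derivation of
    the recursion used as an oracle."""
    A = np.atleast_2d(np.asarray(A, float))
    H = np.atleast_2d(np.asarray(H, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    x = np.asarray(x0, float).reshape(-1, 1)
    P = np.atleast_2d(np.asarray(P0, float))
    out = []
    for zk in np.asarray(z, float):
        x = A @ x
        P = A @ P @ A.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (np.array([[zk]]) - H @ x)
        P = (np.eye(P.shape[0]) - K @ H) @ P
        out.append(float((H @ x)[0, 0]))
    return np.array(out), K.ravel(), P


def exhaustive_two_break(x):
    """Brute-force two-change-point search: explicit segment SSE via slices.

    Same objective and tie-break convention (largest offset, then largest
    onset) as the production detector, but computed independently.
    """
    x = np.asarray(x, float)
    n = x.size

    def sse(seg):
        if seg.size == 0:
            return 0.0
        return float(((seg - seg.mean()) ** 2).sum())

    best_cost, best = np.inf, None
    for i in range(1, n - 1):
        for j in range(i + 1, n):
            c = sse(x[:i]) + sse(x[i:j]) + sse(x[j:])
            tol = 1e-9 * (1.0 + abs(best_cost)) if np.isfinite(best_cost) else 0.0
            if c < best_cost - tol:
                best_cost, best = c, (i, j)
            elif abs(c - best_cost) <= tol and (j, i) > (best[1], best[0]):
                best = (i, j)
    return best


def riccati_fixed_point(A, H, Q, R, iters=200_000, tol=1e-14):
    """Iterate the predicted-covariance Riccati recursion to its fixed point
    and return the steady-state gain (oracle for the running filter)."""
    A = np.atleast_2d(np.asarray(A, float))
    H = np.atleast_2d(np.asarray(H, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    n = A.shape[0]
    P = np.eye(n)
    for _ in range(iters):
        S = (H @ P @ H.T).item() + R
        K = (P @ H.T) / S
        Pp = (np.eye(n) - K @ H) @ P
        Pn = A @ Pp @ A.T + Q
        if np.max(np.abs(Pn - P)) < tol * max(1.0, np.max(np.abs(P))):
            P = Pn
            break
        P = Pn
    S = (H @ P @ H.T).item() + R
    return ((P @ H.T) / S).ravel()
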