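"""Discrete state-space models of the corneo-retinal potential during saccades.

Four state estimators supply the Kalman filter's prediction step:

* **BM** — Brownian motion: the potential is a random walk (n = 1).
* **CVM** — constant velocity: the rate of change of the potential is held
  constant between samples (n = 2); the central model of this package,
  motivated by the near-constant peak velocity of larger saccades.
* **CAM** — constant acceleration: the second rate of change is constant
  (n = 3).
* **LR** — linear reciprocal: a 4th-order companion-form model inspired by
  the agonist-antagonist extraocular-muscle pair; its physiological
  constants C0..C3 are supplied by the caller.

Every model shares the discrete form

    x_k = A x_{k-1} + w_k,   w_k ~ N(0, Q)
    z_k = H x_k     + v_k,   v_k ~ N(0, R)

with no input term (the filters run "free": saccades are driven by visual
cues the electrode does not observe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

MODEL_NAMES = ("BM", "CVM", "CAM", "LR")
Q_STRUCTURES = ("white_noise", "diagonal")

_STATE_LABELS = {
    "BM": ["potential"],
    "CVM": ["potential", "rate"],
    "CAM": ["potential", "rate", "2nd rate"],
    "LR": ["potential", "rate", "2nd rate", "3rd rate"],
}


@dataclass
class StateSpaceModel:
    """Transition/measurement matrices and noise covariances for one estimator.

    Attributes
    ----------
    name : str
        One of ``BM``, ``CVM``, ``CAM``, ``LR``.
    A : (n, n) ndarray
        State transition matrix over one sample interval.
    H : (1, n) ndarray
        Measurement matrix; extracts the potential component.
    Q : (n, n) ndarray
        Process-noise covariance (symmetric PSD), signal-units².
    R : float
        Measurement-noise variance (> 0), signal-units².
    dt : float
        Step duration in seconds.
    state_labels : list of str
        Semantic label per state component.
    """

    name: str
    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: float
    dt: float
    state_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = float(self.R)
        n = self.A.shape[0]
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.A.shape != (n, n) or self.Q.shape != (n, n):
            raise ValueError("A and Q must be square with matching dimension")
        if self.H.shape != (1, n):
            raise ValueError(f"H must be 1x{n}, got {self.H.shape}")
        if self.R <= 0:
            raise ValueError(f"measurement variance R must be positive, got {self.R}")
        if self.dt <= 0:
            raise ValueError(f"step duration dt must be positive, got {self.dt}")
        if not np.allclose(self.Q, self.Q.T, atol=1e-12):
            raise ValueError("Q must be symmetric")
        if np.linalg.eigvalsh((self.Q + self.Q.T) / 2).min() < -1e-10:
            raise ValueError("Q must be positive semidefinite")
        if not self.state_labels:
            self.state_labels = list(_STATE_LABELS[self.name])[:n]

    @property
    def n(self) -> int:
        """State dimension."""
        return self.A.shape[0]


def _kinematic_q(q: float, dt: float, n: int, structure: str) -> np.ndarray:
    """Process covariance for an n-state integrator chain.

    ``white_noise``: Q = q·G·Gᵀ with G the discrete white-noise column
    (G = [dt²/2, dt]ᵀ for n=2, [dt³/6, dt²/2, dt]ᵀ for n=3), the standard
    discrete white-noise-acceleration/jerk form. ``diagonal``: Q = q·I,
    reproducing scalar per-model Q settings literally.
    """
    if structure not in Q_STRUCTURES:
        raise ValueError(f"q_structure must be one of {Q_STRUCTURES}, got {structure!r}")
    if q < 0:
        raise ValueError(f"process-noise intensity q must be >= 0, got {q}")
    if structure == "diagonal":
        return q * np.eye(n)
    g = np.array([dt ** (n - i) / math.factorial(n - i) for i in range(n)])
    return q * np.outer(g, g)


def build_bm(q: float, r: float, dt: float = 1.0 / 250.0) -> StateSpaceModel:
    """Brownian-motion model: the potential is a random walk.

    A = [1], H = [1], Q = [q], R = r. The Kalman filter built on it is an
    adaptive exponential averager.
    """
    if q < 0:
        raise ValueError(f"process-noise intensity q must be >= 0, got {q}")
    return StateSpaceModel("BM", np.array([[1.0]]), np.array([[1.0]]),
                           np.array([[float(q)]]), r, dt)


def build_cvm(dt: float, q: float, r: float,
              q_structure: str = "white_noise") -> StateSpaceModel:
    """Constant-velocity model: state (potential, rate of change).

    A = [[1, dt], [0, 1]], H = [1, 0]. The rate state lets the filter track
    the steep saccadic transition without the lag a random-walk model incurs.
    """
    if dt <= 0:
        raise ValueError(f"step duration dt must be positive, got {dt}")
    A = np.array([[1.0, dt], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    return StateSpaceModel("CVM", A, H, _kinematic_q(q, dt, 2, q_structure), r, dt)


def build_cam(dt: float, q: float, r: float,
              q_structure: str = "white_noise") -> StateSpaceModel:
    """Constant-acceleration model: state (potential, rate, 2nd rate).

    A = [[1, dt, dt²/2], [0, 1, dt], [0, 0, 1]], H = [1, 0, 0].
    """
    if dt <= 0:
        raise ValueError(f"step duration dt must be positive, got {dt}")
    A = np.array([[1.0, dt, dt * dt / 2.0],
                  [0.0, 1.0, dt],
                  [0.0, 0.0, 1.0]])
    H = np.array([[1.0, 0.0, 0.0]])
    return StateSpaceModel("CAM", A, H, _kinematic_q(q, dt, 3, q_structure), r, dt)


def build_lr(constants, dt: float, q: float, r: float,
             q_structure: str = "white_noise") -> StateSpaceModel:
    """Linear-reciprocal model: 4th-order companion form of the
    agonist-antagonist extraocular-muscle dynamics.

    The continuous system matrix is the companion form

        [[0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1], [-C0, -C1, -C2, -C3]]

    discretized by zero-order hold (matrix exponential over dt, no input).
    The physiological constants C0..C3 come from extraocular-muscle
    parameters and must be supplied by the caller.
    """
    if dt <= 0:
        raise ValueError(f"step duration dt must be positive, got {dt}")
    c = np.asarray(constants, dtype=float).ravel()
    if c.size != 4 or not np.all(np.isfinite(c)):
        raise ValueError("LR model requires four finite constants C0..C3")
    Ac = np.zeros((4, 4))
    Ac[0, 1] = Ac[1, 2] = Ac[2, 3] = 1.0
    Ac[3, :] = -c
    A = expm(Ac * dt)
    if not np.all(np.isfinite(A)):
        raise FloatingPointError("LR discretization produced non-finite entries")
    H = np.array([[1.0, 0.0, 0.0, 0.0]])
    if q_structure == "diagonal":
        Q = _kinematic_q(q, dt, 4, "diagonal")
    else:
        # white noise enters the last state (companion input channel);
        # G_d = ∫0^dt expm(Ac s) e4 ds via the augmented-exponential trick.
        M = np.zeros((5, 5))
        M[:4, :4] = Ac
        M[:4, 4] = [0.0, 0.0, 0.0, 1.0]
        Md = expm(M * dt)
        g = Md[:4, 4]
        Q = q * np.outer(g, g)
    model = StateSpaceModel("LR", A, H, Q, r, dt)
    return model


_BUILDERS = {"bm": build_bm, "cvm": build_cvm, "cam": build_cam, "lr": build_lr}


def build_model(name: str, dt: float, q: float, r: float,
                q_structure: str = "white_noise",
                lr_constants=None) -> StateSpaceModel:
    """Dispatch by lowercase model name (``bm``, ``cvm``, ``cam``, ``lr``)."""
    key = name.lower()
    if key == "bm":
        return build_bm(q, r, dt)
    if key == "cvm":
        return build_cvm(dt, q, r, q_structure)
    if key == "cam":
        return build_cam(dt, q, r, q_structure)
    if key == "lr":
        if lr_constants is None:
            raise ValueError("LR model requires lr_constants=(C0, C1, C2, C3)")
        return build_lr(lr_constants, dt, q, r, q_structure)
    raise ValueError(f"unknown model {name!r}; expected one of bm/cvm/cam/lr")
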