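"""Evaluation battery: error definitions, SNR, normalized-error summaries,
feature correlations, and the main-sequence fit.

Amplitude errors come in two flavors: against the reference eye tracker
(|θ_EOG − θ_EL|) and against the physical target angle (|θ − θ_true|).
The normalized error (measured − true)/true summarizes accuracy (mean) and
precision (variance) of a method; its distribution is rendered as a
Gaussian kernel density. Peak velocity versus amplitude is fitted to the
saccadic main sequence V_p = a1·(1 − e^(−θ/a2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .timeseries import TimeSeries


@dataclass
class TrialErrors:
    """Per-trial amplitude errors (degrees; ``e_norm`` is a signed fraction)."""

    e_eog_el: float
    e_abs_eog: float
    e_abs_el: float
    e_norm: float


@dataclass
class MainSequenceParams:
    """Main-sequence fit: V_p = a1·(1 − e^(−θ/a2)).

    ``a1`` is the peak-velocity asymptote (deg/s), ``a2`` the amplitude
    constant (deg), ``rmse`` the residual RMS in deg/s.
    """

    a1: float
    a2: float
    rmse: float

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("main-sequence constants must be positive")

    def velocity(self, theta):
        return self.a1 * (1.0 - np.exp(-np.abs(np.asarray(theta, float)) / self.a2))


def main_sequence_velocity(theta, a1: float, a2: float):
    """V_p = a1·(1 − e^(−θ/a2)) on amplitude magnitudes."""
    return a1 * (1.0 - np.exp(-np.abs(np.asarray(theta, dtype=float)) / a2))


def compute_errors(theta_eog: float, theta_el: float, theta_true: float) -> TrialErrors:
    """The four per-trial error quantities; ``theta_true`` must be nonzero."""
    if theta_true == 0:
        raise ValueError("true angle must be nonzero for the normalized error")
    return TrialErrors(
        e_eog_el=abs(theta_eog - theta_el),
        e_abs_eog=abs(theta_eog - theta_true),
        e_abs_el=abs(theta_el - theta_true),
        e_norm=(theta_eog - theta_true) / theta_true,
    )


def snr_db(raw: TimeSeries | np.ndarray, filtered: TimeSeries | np.ndarray,
           literal: bool = False) -> float:
    """Signal-to-noise ratio of a filtered signal against the raw one, in dB.

    Power-ratio form (default): 10·log10( Σ f² / Σ (raw − f)² ). With
    ``literal=True`` the unsquared sums 10·log10( Σ f / Σ (raw − f) ) are
    used instead (only meaningful for positive sums).
    """
    r = raw.values if isinstance(raw, TimeSeries) else np.asarray(raw, float)
    f = filtered.values if isinstance(filtered, TimeSeries) else np.asarray(filtered, float)
    if r.size != f.size:
        raise ValueError("raw and filtered must have equal length")
    resid = r - f
    if literal:
        num, den = float(np.sum(f)), float(np.sum(resid))
        if den == 0:
            raise ZeroDivisionError("zero residual sum: SNR is infinite")
        return 10.0 * np.log10(num / den)
    p_sig = float(np.sum(f * f))
    p_res = float(np.sum(resid * resid))
    if p_res == 0:
        raise ZeroDivisionError("zero residual power: SNR is infinite")
    return 10.0 * np.log10(p_sig / p_res)


def normalized_error_summary(errors, grid_points: int = 256, percent: bool = False):
    """Mean, variance and Gaussian kernel density of normalized errors.

    Expects outlier-cleaned input. Bandwidth follows Silverman's rule; the
    evaluation grid spans the data range ± 3 bandwidths. ``percent`` scales
    errors by 100 before summarizing. Returns
    ``(mean, variance, (grid, density))``.
    """
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("no errors supplied")
    if percent:
        e = 100.0 * e
    mu = float(np.mean(e))
    var = float(np.var(e))
    sd = np.std(e)
    if sd <= 1e-12 * max(1.0, abs(mu)):
        # degenerate sample: delta-like density on a token grid
        grid = np.linspace(mu - 1.0, mu + 1.0, grid_points)
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - mu))] = 1.0 / (grid[1] - grid[0])
        return mu, var, (grid, dens)
    bw = 0.9 * min(sd, stats.iqr(e) / 1.34 if stats.iqr(e) > 0 else sd) * e.size ** (-1 / 5)
    kde = stats.gaussian_kde(e, bw_method=bw / sd)
    grid = np.linspace(e.min() - 3 * bw, e.max() + 3 * bw, grid_points)
    return mu, var, (grid, kde(grid))


def feature_correlation(x, y) -> float:
    """Pearson correlation between two feature lists."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length lists of at least 2 values")
    return float(stats.pearsonr(x, y).statistic)


def fit_main_sequence(thetas, vpeaks) -> MainSequenceParams:
    """Nonlinear least squares of the main sequence on (|θ|, V_p) pairs.

    Initialization: a1 = max(V_p), a2 = median(|θ|); both bounded positive.
    """
    th = np.abs(np.asarray(thetas, dtype=float).ravel())
    vp = np.asarray(vpeaks, dtype=float).ravel()
    if th.size != vp.size:
        raise ValueError("thetas and vpeaks must have equal length")
    if np.unique(th).size < 3:
        raise ValueError("need at least 3 distinct amplitudes")
    p0 = (max(vp.max(), 1e-6), max(np.median(th), 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            main_sequence_velocity, th, vp, p0=p0,
            bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics passthrough
        raise RuntimeError(f"main-sequence fit did not converge: {exc}") from exc
    resid = vp - main_sequence_velocity(th, *popt)
    return MainSequenceParams(a1=float(popt[0]), a2=float(popt[1]),
                              rmse=float(np.sqrt(np.mean(resid ** 2))))


def two_sample_ttest(a, b):
    """Plain two-sample Welch t-test (report plumbing): returns (t, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)
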