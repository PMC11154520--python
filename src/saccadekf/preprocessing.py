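"""Trial segmentation, detrending, microvolt→degree calibration, outliers.

Calibration follows the peak-average scheme: during a calibration block the
participant makes repeated saccades to four known targets (−22°, −11°,
+11°, +22°); fixation-plateau peaks of the EOG are averaged per target and
an ordinary least-squares line of peak average versus target angle yields
the calibration factor K (µV per degree) and intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats

from .timeseries import TimeSeries

#: Target label → angle in degrees of visual angle. A and B lie left of the
#: home position (negative), C and D right (positive).
TARGET_ANGLES = {"A": -22.0, "B": -11.0, "C": 11.0, "D": 22.0}

MARKER_LABELS = ("start", "cue", "ping", "end")


@dataclass
class TrialRecord:
    """One trial: EOG trace, optional reference gaze trace, event markers."""

    eog: TimeSeries
    markers: list  # of (label, time_seconds)
    target: str
    reference: TimeSeries | None = None
    target_angle: float | None = None

    def __post_init__(self) -> None:
        if self.target not in TARGET_ANGLES:
            raise ValueError(f"unknown target {self.target!r}")
        if self.target_angle is None:
            self.target_angle = TARGET_ANGLES[self.target]
        elif self.target_angle != TARGET_ANGLES[self.target]:
            raise ValueError(
                f"target {self.target} implies {TARGET_ANGLES[self.target]}°, "
                f"got {self.target_angle}"
            )
        times = [t for _, t in self.markers]
        if times != sorted(times):
            raise ValueError("markers must be sorted by time")
        labels = [l for l, _ in self.markers]
        for l in labels:
            if l not in MARKER_LABELS:
                raise ValueError(f"unknown marker label {l!r}")
        if "start" in labels and "end" in labels:
            if self.marker_time("start") > self.marker_time("end"):
                raise ValueError("start marker must precede end marker")

    def marker_time(self, label: str) -> float:
        for l, t in self.markers:
            if l == label:
                return t
        raise KeyError(f"no {label!r} marker in trial")

    def has_marker(self, label: str) -> bool:
        return any(l == label for l, _ in self.markers)


@dataclass
class CalibrationModel:
    """Linear map between microvolts and degrees.

    ``K`` is the slope in µV per degree, ``intercept`` the µV offset at 0°.
    ``per_target_peak_averages`` records the pooled peak average per target.
    """

    K: float
    intercept: float
    per_target_peak_averages: dict = field(default_factory=dict)
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.K) or self.K == 0:
            raise ValueError(f"calibration slope K must be finite and nonzero, got {self.K}")

    def microvolts_to_degrees(self, uv):
        return (np.asarray(uv, dtype=float) - self.intercept) / self.K

    def degrees_to_microvolts(self, deg):
        return np.asarray(deg, dtype=float) * self.K + self.intercept


def detrend_piecewise(trial: TrialRecord, order: int = 1,
                      baseline_tail_s: float = 0.2) -> TrialRecord:
    """Remove polynomial drift between the trial markers and zero the baseline.

    The drift polynomial is estimated where the eye is known to fixate the
    home position — the start→cue window and the trailing
    ``baseline_tail_s`` seconds before the end marker — and subtracted over
    the whole start→end segment. Anchoring the fit on home-fixation samples
    rectifies drift without absorbing any of the saccadic excursion, and
    simultaneously normalizes the isolated saccade to a zero baseline.
    Trials without a cue marker fall back to a plain per-segment polynomial
    fit between consecutive markers.
    """
    if order < 1:
        raise ValueError(f"detrend order must be >= 1, got {order}")
    x = trial.eog.values.copy()
    t = trial.eog.times
    n = len(x)
    fit = np.polynomial.polynomial

    if trial.has_marker("cue"):
        a = trial.eog.index_at(trial.marker_time("start")) if trial.has_marker("start") else 0
        b = (trial.eog.index_at(trial.marker_time("end")) + 1) if trial.has_marker("end") else n
        cue = trial.eog.index_at(trial.marker_time("cue"))
        tail = max(1, int(round(baseline_tail_s * trial.eog.fs)))
        base_idx = np.r_[np.arange(a, max(a + 1, cue)), np.arange(max(a, b - tail), b)]
        base_idx = np.unique(base_idx)
        if base_idx.size < order + 2:
            raise ValueError(
                f"baseline windows hold {base_idx.size} samples; too short "
                f"for order-{order} detrend"
            )
        coef = fit.polyfit(t[base_idx] - t[a], x[base_idx], order)
        x[a:b] -= fit.polyval(t[a:b] - t[a], coef)
        return replace(trial, eog=trial.eog.with_values(x))

    inner = [trial.eog.index_at(mt) for _, mt in trial.markers]
    # markers within a fit-width of the record edges delimit no usable
    # segment of their own; merge them into the boundary
    inner = [e for e in inner if order + 2 <= e <= n - (order + 2)]
    edges = sorted(set([0] + inner + [n]))
    for seg_i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        if b - a < order + 2:
            raise ValueError(
                f"segment {seg_i} (samples {a}:{b}) too short for order-{order} detrend"
            )
        coef = fit.polyfit(t[a:b] - t[a], x[a:b], order)
        x[a:b] -= fit.polyval(t[a:b] - t[a], coef)
    return replace(trial, eog=trial.eog.with_values(x))


def _qualifying_peaks(x: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of local maxima with value ≥ min + threshold·(max − min)."""
    if x.size < 3:
        raise ValueError("signal too short for peak detection")
    lo, hi = float(x.min()), float(x.max())
    height = lo + threshold * (hi - lo)
    idx, _ = sps.find_peaks(x, height=height if hi > lo else None, plateau_size=1)
    return idx


def peak_average(signal: TimeSeries, threshold: float = 0.8):
    """Mean of local-maximum values above a min–max range threshold.

    A peak qualifies if its value ≥ min + threshold·(max − min). Flat-topped
    (plateau) peaks count once at their plateau value. Returns
    ``(mean_peak_value, n_peaks)``.
    """
    x = signal.values
    idx = _qualifying_peaks(x, threshold)
    if idx.size == 0:
        raise ValueError(f"no peaks above the {threshold:.0%} min-max threshold")
    return float(x[idx].mean()), int(idx.size)


def fit_calibration(cal_trials, threshold: float = 0.8) -> CalibrationModel:
    """OLS of pooled per-target peak averages against target angle.

    For negative (leftward) targets the fixation plateau is a trough, so
    peaks are detected on the negated trace and their sign restored. Peaks
    are pooled across all calibration trials of each target before
    averaging. Requires at least two distinct target angles.
    """
    pooled: dict[str, list[float]] = {}
    for trial in cal_trials:
        sign = 1.0 if TARGET_ANGLES[trial.target] >= 0 else -1.0
        oriented = sign * trial.eog.values
        idx = _qualifying_peaks(oriented, threshold)
        if idx.size == 0:
            raise ValueError(
                f"no qualifying peaks in a {trial.target} calibration trial"
            )
        pooled.setdefault(trial.target, []).extend((sign * oriented[idx]).tolist())
    if len({TARGET_ANGLES[t] for t in pooled}) < 2:
        raise ValueError("calibration requires >= 2 distinct target angles")
    targets = sorted(pooled, key=lambda t: TARGET_ANGLES[t])
    angles = np.array([TARGET_ANGLES[t] for t in targets])
    peaks = np.array([float(np.mean(pooled[t])) for t in targets])
    res = stats.linregress(angles, peaks)
    return CalibrationModel(
        K=float(res.slope),
        intercept=float(res.intercept),
        per_target_peak_averages={t: float(np.mean(pooled[t])) for t in targets},
        r_squared=float(res.rvalue ** 2),
    )


def fit_calibration_from_features(cal_trials, extractor) -> CalibrationModel:
    """Calibration from baseline-referenced saccade amplitudes.

    ``extractor`` maps a TrialRecord to its extracted amplitude in the
    trial's own units (here µV). Using the *same* statistic for calibration
    and later feature extraction makes the µV→degree map self-consistent:
    residual drift, filter overshoot and noise-peak biases enter numerator
    and denominator alike and cancel in the ratio. Per-target amplitudes
    are averaged over trials, then OLS against target angle gives K and the
    intercept.
    """
    pooled: dict[str, list[float]] = {}
    for trial in cal_trials:
        pooled.setdefault(trial.target, []).append(float(extractor(trial)))
    if len({TARGET_ANGLES[t] for t in pooled}) < 2:
        raise ValueError("calibration requires >= 2 distinct target angles")
    targets = sorted(pooled, key=lambda t: TARGET_ANGLES[t])
    angles = np.array([TARGET_ANGLES[t] for t in targets])
    amps = np.array([float(np.mean(pooled[t])) for t in targets])
    res = stats.linregress(angles, amps)
    return CalibrationModel(
        K=float(res.slope),
        intercept=float(res.intercept),
        per_target_peak_averages={t: float(np.mean(pooled[t])) for t in targets},
        r_squared=float(res.rvalue ** 2),
    )


def apply_calibration(signal: TimeSeries, cal: CalibrationModel) -> TimeSeries:
    """Convert a microvolt trace to degrees: (µV − intercept) / K."""
    return signal.with_values(cal.microvolts_to_degrees(signal.values), unit="degree")


def remove_outliers_iqr(values, multiplier: float = 1.5):
    """Keep values inside [Q1 − m·IQR, Q3 + m·IQR]; report the removed fraction.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention). Requires at least 4 values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise ValueError(f"need >= 4 values for IQR fences, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation by default
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    mask = (v >= lo) & (v <= hi)
    kept = v[mask]
    return kept, float(1.0 - kept.size / v.size)


def estimate_measurement_variance(cal_trials, detrend_order: int = 1) -> float:
    """Measurement-noise variance R from calibration trials.

    Uses the median-absolute first difference of each detrended calibration
    trace as a robust high-frequency noise estimate (saccadic transitions
    are sparse, so differences are dominated by sensor noise), averaged
    across trials. Returns a variance in signal units².
    """
    sds = []
    for trial in cal_trials:
        try:
            trial = detrend_piecewise(trial, detrend_order)
        except ValueError:
            pass
        d = np.diff(trial.eog.values)
        if d.size == 0:
            continue
        # robust sigma of x from diff: sigma_diff = sqrt(2)*sigma
        sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        sds.append(sigma)
    if not sds:
        raise ValueError("no usable calibration trials")
    return float(np.mean(sds) ** 2)
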