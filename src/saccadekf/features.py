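"""Saccade parameter extraction: amplitude, peak velocity, latency.

A trial window (cue → end marker) is segmented by exactly two mean-shift
change points, found by exact least-squares: the pair of break indices
minimizing the total within-segment sum of squared deviations from segment
means. On a step-and-hold-and-return trial the two breaks bracket the
excursion away from the home position (saccade onset and the return
transition); fixation-plateau peaks between them define the amplitude, the
maximum absolute derivative inside them the peak velocity, and the time
from the audio cue to the (velocity-refined) onset the latency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocessing import TrialRecord
from .timeseries import TimeSeries

log = logging.getLogger(__name__)


class NoSaccadeError(ValueError):
    """Raised when a trial window contains no detectable saccade."""


@dataclass
class SaccadeFeatures:
    """Per-trial saccade parameters.

    theta: signed amplitude in degrees; v_peak: peak velocity magnitude in
    deg/s; t_lat: cue-to-onset latency in seconds; changepoints: (onset
    break, offset break) sample indices; n_peaks_averaged: how many fixation
    peaks defined the amplitude (0 means the segment-mean fallback).
    """

    theta: float
    v_peak: float
    t_lat: float
    changepoints: tuple
    n_peaks_averaged: int = 0

    def __post_init__(self) -> None:
        onset, offset = self.changepoints
        if not onset < offset:
            raise ValueError("onset index must precede offset index")
        if self.v_peak < 0:
            raise ValueError("peak velocity is reported as a magnitude")


def detect_changepoints(signal: TimeSeries, n_points: int = 2,
                        min_variance: float = 1e-10):
    """Exact two-break mean-shift segmentation.

    Minimizes SSE(0,i) + SSE(i,j) + SSE(j,n) over all 1 ≤ i < j ≤ n−1 using
    prefix sums (O(n²) pairs, O(1) per pair). Ties are broken toward the
    largest offset, then the largest onset, so that on a step-and-hold
    signal the offset lands at the end of the hold. Returns ``(i, j)``:
    each break is the first index of its new segment.
    """
    if n_points != 2:
        raise NotImplementedError("only the two-change-point case is supported")
    x = signal.values
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if float(np.var(x)) <= min_variance:
        raise NoSaccadeError("signal variance below tolerance; no saccade present")

    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(a, b):
        # SSE of segment [a, b) about its mean; a, b broadcastable arrays
        m = b - a
        s = cs[b] - cs[a]
        return (cs2[b] - cs2[a]) - s * s / m

    i_all = np.arange(1, n - 1)
    best = (np.inf, -1, -1)  # cost, j, i
    left = seg_cost(np.zeros_like(i_all), i_all)
    for k, i in enumerate(i_all):
        j = np.arange(i + 1, n)
        cost = left[k] + seg_cost(np.full_like(j, i), j) + seg_cost(j, np.full_like(j, n))
        # prefer the largest j among ties: scan reversed
        rev = cost[::-1]
        jj = int(j[-1 - int(np.argmin(rev))])
        c = float(cost[jj - (i + 1)])
        scale = 1e-9 * (1.0 + abs(best[0]) if np.isfinite(best[0]) else 1.0)
        if c < best[0] - scale:
            best = (c, jj, int(i))
        elif abs(c - best[0]) <= scale:
            if (jj, int(i)) > (best[1], best[2]):
                best = (best[0], jj, int(i))
    return best[2], best[1]


def _baseline(x: np.ndarray, onset: int, fs: float, window_s: float = 0.05) -> float:
    """Median of the 50 ms preceding the onset (whatever part exists)."""
    w = max(1, int(round(window_s * fs)))
    a = max(0, onset - w)
    if a == onset:
        return float(x[0])
    return float(np.median(x[a:onset]))


def extract_amplitude(signal: TimeSeries, changepoints,
                      prominence_frac: float = 0.0,
                      baseline_window_s: float = 0.05,
                      baseline_index: int | None = None):
    """Signed amplitude: average of fixation peaks between the change points.

    Peaks are located on the magnitude trace (signal minus pre-onset
    baseline, oriented by step direction); the sign of the step is then
    restored. By default every local maximum counts — the same statistic
    the calibration peak average uses, so the noise-peak bias cancels
    between calibration and extraction. ``prominence_frac`` > 0 restricts
    to peaks whose prominence exceeds that fraction of the segment range.
    If no peak qualifies, the segment mean is used (logged). Returns
    ``(theta_degrees, n_peaks_averaged)``.
    """
    onset, offset = changepoints
    x = signal.values
    if not (0 <= onset < offset < x.size):
        raise ValueError(f"invalid changepoints {changepoints} for length {x.size}")
    b_idx = onset if baseline_index is None else baseline_index
    base = _baseline(x, b_idx, signal.fs, baseline_window_s)
    # include one sample before the onset break so a plateau starting at the
    # break itself still registers as an interior (flat) peak
    lo = max(onset - 1, 0)
    seg = x[lo : offset + 1]
    direction = 1.0 if float(np.mean(seg)) - base >= 0 else -1.0
    y = direction * (seg - base)
    rng = float(y.max() - y.min())
    prom = prominence_frac * rng if (prominence_frac > 0 and rng > 0) else None
    idx, _ = sps.find_peaks(y, prominence=prom, plateau_size=1)
    if idx.size == 0:
        log.info("no qualifying peaks between changepoints; using segment mean")
        return direction * float(np.mean(y)), 0
    return direction * float(y[idx].mean()), int(idx.size)


def extract_latency(trial: TrialRecord, onset_index: int) -> float:
    """Latency: time of the onset change point minus the audio-cue time."""
    if not trial.has_marker("cue"):
        raise ValueError("trial has no cue marker")
    t_onset = trial.eog.t0 + onset_index / trial.eog.fs
    t_lat = t_onset - trial.marker_time("cue")
    if t_lat < 0:
        warnings.warn(f"saccade onset precedes the cue (latency {t_lat:.3f} s)")
    return float(t_lat)


def extract_peak_velocity(signal: TimeSeries, changepoints) -> float:
    """Peak velocity: max |central-difference derivative| in the window, deg/s."""
    onset, offset = changepoints
    if offset - onset < 2:
        raise ValueError("fewer than 3 samples between changepoints")
    v = np.gradient(signal.values, signal.dt)  # central diff, one-sided edges
    return float(np.max(np.abs(v[onset : offset + 1])))


def refine_onset(signal: TimeSeries, coarse_onset: int, offset: int,
                 frac: float = 0.02, floor_dps: float = 5.0) -> int:
    """Walk the mean-shift onset back to where velocity leaves the noise floor.

    Mean-shift segmentation puts the break near the middle of the saccadic
    transition; latency needs the transition *start*. From the coarse break,
    step backward while the absolute velocity stays above
    max(frac · window peak velocity, floor) deg/s.
    """
    v = np.abs(np.gradient(signal.values, signal.dt))
    vmax = float(v[coarse_onset : offset + 1].max()) if offset > coarse_onset else float(v[coarse_onset])
    thr = max(frac * vmax, floor_dps)
    k = int(coarse_onset)
    while k > 0 and v[k - 1] > thr:
        k -= 1
    return k


def extract_saccade_features(trial: TrialRecord,
                             prominence_frac: float = 0.0) -> SaccadeFeatures:
    """Full per-trial extraction on a calibrated (degrees) trial.

    Works on the cue→end window so the two change points bracket the
    outbound saccade plus fixation. The onset used for latency is the
    velocity-refined transition start; the raw change-point pair is kept in
    ``changepoints``.
    """
    t_cue = trial.marker_time("cue")
    t_end = trial.marker_time("end") if trial.has_marker("end") else trial.eog.times[-1]
    window = trial.eog.slice_time(t_cue, t_end)
    onset, offset = detect_changepoints(window)
    # the mean-shift break lands mid-transition; reference the baseline to
    # the velocity-refined transition start instead
    onset_refined = refine_onset(window, onset, offset)
    theta, n_pk = extract_amplitude(window, (onset, offset), prominence_frac,
                                    baseline_index=onset_refined)
    v_peak = extract_peak_velocity(window, (onset, offset))
    i0 = trial.eog.index_at(window.t0)
    trial_window = TrialRecord(eog=trial.eog, markers=trial.markers,
                               target=trial.target, reference=trial.reference)
    t_lat = extract_latency(trial_window, i0 + onset_refined)
    return SaccadeFeatures(theta=theta, v_peak=v_peak, t_lat=t_lat,
                           changepoints=(onset, offset), n_peaks_averaged=n_pk)
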