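"""Ground-truthed synthetic EOG trials.

Each trial emulates one cue-directed horizontal saccade: the gaze angle
rests at the home position, steps to one of four targets (−22°, −11°, +11°,
+22°) after a sampled latency, holds fixation, and returns home after a
"ping" cue. The clean electrode potential is K_true·angle (the linear
corneo-retinal relation); the measured EOG adds Gaussian sensor noise,
low-frequency baseline drift, 60 Hz line interference and optional blink
bumps. A low-noise reference trace in degrees stands in for the video eye
tracker channel.

Saccade kinematics obey the main sequence: the peak velocity of an
amplitude-θ saccade is V_p = a1·(1 − e^(−|θ|/a2)), and the product
V_p·D = |θ| defines the effective duration D. The velocity profile is a
raised-cosine pulse of total length 2D, which makes the peak velocity
exactly V_p and the displacement exactly θ (a raised cosine has mean
velocity half its peak, so the constant-velocity-equivalent duration D is
half the pulse length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import SaccadeFeatures
from .metrics import main_sequence_velocity
from .preprocessing import TARGET_ANGLES, TrialRecord
from .timeseries import TimeSeries


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Units: fs in Hz, angles in degrees, potentials in µV, times in seconds.
    ``K_true`` defaults to the textbook horizontal EOG sensitivity of
    ~16 µV per degree of visual angle; a1/a2 are literature-typical
    main-sequence constants. ``noise_snr_db``, when set, overrides
    ``noise_sigma`` by planting a per-trial clean-power/noise-power ratio.
    ``seed`` fixes all randomness.
    """

    fs: float = 250.0
    a1: float = 500.0  # deg/s, main-sequence velocity asymptote
    a2: float = 15.0  # deg, main-sequence amplitude constant
    K_true: float = 16.0  # µV per degree
    noise_sigma: float = 15.0  # µV additive Gaussian noise when no SNR is planted
    noise_snr_db: float | None = 6.0  # plant this clean/noise power ratio per trial
    drift_amp_uv: float = 50.0  # RMS of baseline drift
    drift_corner_hz: float = 0.1
    line_amp_60hz: float = 5.0  # µV amplitude of mains interference
    blink_rate: float = 0.1  # expected blinks per trial
    blink_amp_uv: float = 400.0
    blink_duration_s: float = 0.2
    latency_mean: float = 0.18
    latency_sd: float = 0.03
    gain_sd: float = 0.1  # saccadic endpoint variability (multiplicative)
    fixation_jitter_s: float = 0.2  # uniform +/- jitter of fixation duration
    el_noise_deg: float = 0.05  # reference-channel noise
    pre_cue_s: float = 1.0
    fixation_s: float = 1.0
    post_return_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("noise_sigma", "drift_amp_uv", "line_amp_60hz",
                     "blink_rate", "blink_amp_uv", "el_noise_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTrial:
    """One generated trial with full ground truth."""

    truth_angle: TimeSeries
    clean_potential: TimeSeries
    noisy_eog: TimeSeries
    reference_trace: TimeSeries
    markers: list
    target: str
    ground_truth: SaccadeFeatures
    artifacts: list = field(default_factory=list)

    def to_trial_record(self, which: str = "noisy") -> TrialRecord:
        """View as a TrialRecord (``which``: noisy | clean | reference)."""
        sig = {"noisy": self.noisy_eog, "clean": self.clean_potential,
               "reference": self.reference_trace}[which]
        return TrialRecord(eog=sig, markers=self.markers, target=self.target,
                           reference=self.reference_trace)


def generate_saccade_waveform(theta: float, cfg: GeneratorConfig):
    """Angle trace of one saccade plus its true peak velocity and duration.

    Returns ``(angle, v_peak, duration)`` where ``angle`` is a TimeSeries
    starting at 0° and settling at ``theta``; ``v_peak`` = a1(1 − e^(−|θ|/a2))
    deg/s and ``duration`` = |θ|/V_p seconds (the constant-velocity
    equivalent; the emitted pulse spans twice that). The closed-form
    position of the raised-cosine pulse of length T = 2·duration is
    x(t) = sign(θ)·(V_p/2)·(t − (T/2π)·sin(2πt/T)).
    """
    if theta == 0:
        raise ValueError("saccade amplitude must be nonzero")
    v_peak = float(main_sequence_velocity(theta, cfg.a1, cfg.a2))
    duration = abs(theta) / v_peak
    T = 2.0 * duration
    n = int(np.ceil(T * cfg.fs)) + 1  # last sample lands at or beyond T
    if n < 3:
        raise ValueError(
            f"saccade of {theta}° spans {n} samples at {cfg.fs} Hz; infeasible"
        )
    t = np.arange(n) / cfg.fs
    x = (v_peak / 2.0) * (t - (T / (2 * np.pi)) * np.sin(2 * np.pi * t / T))
    x = np.clip(x, 0.0, abs(theta))
    x[t >= T] = abs(theta)
    angle = TimeSeries(np.sign(theta) * x, cfg.fs, unit="degree")
    return angle, v_peak, duration


def _one_pole_lowpass_drift(n: int, cfg: GeneratorConfig, rng: np.random.Generator):
    """White noise through a single-pole low-pass, scaled to the target RMS."""
    if cfg.drift_amp_uv == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    alpha = np.exp(-2 * np.pi * cfg.drift_corner_hz / cfg.fs)
    d = sps.lfilter([1 - alpha], [1, -alpha], w)
    rms = np.sqrt(np.mean(d * d))
    return cfg.drift_amp_uv * d / rms if rms > 0 else d


def _blink_pulse(n_samples: int) -> np.ndarray:
    """Raised-cosine bump of unit amplitude."""
    t = np.linspace(0, 1, n_samples)
    return 0.5 * (1 - np.cos(2 * np.pi * t))


def generate_trial(target: str, cfg: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> SyntheticTrial:
    """One full trial for a target: out-saccade, fixation, return, artifacts."""
    if target not in TARGET_ANGLES:
        raise ValueError(f"unknown target {target!r}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    target_angle = TARGET_ANGLES[target]
    # saccadic endpoint variability: the eye lands near, not on, the target
    gain = max(0.5, rng.normal(1.0, cfg.gain_sd)) if cfg.gain_sd > 0 else 1.0
    theta = gain * target_angle
    out_wave, v_peak, duration = generate_saccade_waveform(theta, cfg)

    lat_out = max(0.05, rng.normal(cfg.latency_mean, cfg.latency_sd))
    lat_ret = max(0.05, rng.normal(cfg.latency_mean, cfg.latency_sd))
    fixation = max(0.3, cfg.fixation_s + rng.uniform(-1, 1) * cfg.fixation_jitter_s)

    t_cue = cfg.pre_cue_s
    t_onset = t_cue + lat_out
    t_fix_start = t_onset + 2 * duration
    t_ping = t_fix_start + fixation
    t_ret_onset = t_ping + lat_ret
    t_ret_end = t_ret_onset + 2 * duration
    t_end = t_ret_end + cfg.post_return_s

    n = int(np.ceil(t_end * cfg.fs)) + 1
    angle = np.zeros(n)
    i_on = int(round(t_onset * cfg.fs))
    i_ret = int(round(t_ret_onset * cfg.fs))
    m = len(out_wave)
    angle[i_on : i_on + m] = out_wave.values
    angle[i_on + m :] = theta
    ret = theta - out_wave.values  # mirror pulse back to home
    angle[i_ret : i_ret + m] = ret[: max(0, n - i_ret)]
    angle[i_ret + m :] = 0.0

    truth = TimeSeries(angle, cfg.fs, unit="degree")
    clean = TimeSeries(cfg.K_true * angle, cfg.fs, unit="microvolt")

    if cfg.noise_snr_db is not None:
        p_clean = float(np.mean(clean.values ** 2))
        sigma = np.sqrt(p_clean / 10 ** (cfg.noise_snr_db / 10.0))
    else:
        sigma = cfg.noise_sigma
    noise = sigma * rng.standard_normal(n)
    drift = _one_pole_lowpass_drift(n, cfg, rng)
    t = truth.times
    phase = rng.uniform(0, 2 * np.pi)
    line = cfg.line_amp_60hz * np.sin(2 * np.pi * 60.0 * t + phase)

    artifacts = []
    blink = np.zeros(n)
    n_blinks = rng.poisson(cfg.blink_rate)
    nb = max(3, int(round(cfg.blink_duration_s * cfg.fs)))
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(1, n - nb)))
        blink[start : start + nb] += cfg.blink_amp_uv * _blink_pulse(nb)
        artifacts.append(("blink", (start / cfg.fs, (start + nb) / cfg.fs)))
    if cfg.drift_amp_uv > 0:
        artifacts.append(("drift", (0.0, n / cfg.fs)))
    if cfg.line_amp_60hz > 0:
        artifacts.append(("line", (0.0, n / cfg.fs)))

    noisy = TimeSeries(clean.values + noise + drift + line + blink,
                       cfg.fs, unit="microvolt")
    reference = TimeSeries(angle + cfg.el_noise_deg * rng.standard_normal(n),
                           cfg.fs, unit="degree")
    markers = [("start", 0.0), ("cue", t_cue), ("ping", t_ping), ("end", (n - 1) / cfg.fs)]
    gt = SaccadeFeatures(theta=theta, v_peak=v_peak, t_lat=lat_out,
                         changepoints=(i_on, i_ret), n_peaks_averaged=0)
    return SyntheticTrial(truth_angle=truth, clean_potential=clean,
                          noisy_eog=noisy, reference_trace=reference,
                          markers=markers, target=target, ground_truth=gt,
                          artifacts=artifacts)


def generate_session(n_cal_per_target: int = 5, n_exp_trials: int = 20,
                     cfg: GeneratorConfig | None = None):
    """Calibration block then a pseudo-random experimental block.

    The calibration block holds ``n_cal_per_target`` consecutive trials per
    target (A, B, C, D in order); the experimental block draws targets in a
    seed-reproducible shuffled balanced order. Returns
    ``(cal_trials, exp_trials)`` as lists of :class:`SyntheticTrial`.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    cal = [generate_trial(tgt, cfg, rng)
           for tgt in "ABCD" for _ in range(n_cal_per_target)]
    order = [("ABCD")[i % 4] for i in range(n_exp_trials)]
    order = list(rng.permutation(order))
    exp = [generate_trial(tgt, cfg, rng) for tgt in order]
    return cal, exp


def sigma_for_snr(clean: TimeSeries, snr_db_target: float) -> float:
    """Gaussian σ that plants the requested clean-power/noise-power ratio."""
    p_clean = float(np.mean(clean.values ** 2))
    return float(np.sqrt(p_clean / 10 ** (snr_db_target / 10.0)))
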