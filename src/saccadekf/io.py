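"""Delimited-text I/O for trials, markers, features and calibration models.

Trial files are CSV with columns ``time,eog_uv[,ref_deg]`` (times in
seconds); marker files are CSV with columns ``time,label``. The sampling
rate is inferred from the median inter-sample interval and must be uniform
to within 1% jitter.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import CalibrationModel, TrialRecord
from .timeseries import TimeSeries


def _infer_fs(time: np.ndarray, path) -> float:
    dt = np.diff(time)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time column not strictly increasing at row {bad[0] + 1}"
        )
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        worst = int(np.argmax(np.abs(dt - med)))
        raise ValueError(
            f"{path}: inconsistent sample interval at row {worst + 1} "
            f"(dt={dt[worst]:.6g}, median {med:.6g})"
        )
    return 1.0 / med


def read_markers_csv(path) -> list:
    """Read a ``time,label`` marker file into a sorted (label, time) list."""
    df = pd.read_csv(path, comment="#")
    for col in ("time", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [(str(l), float(t)) for t, l in
            sorted(zip(df["time"], df["label"]))]


def read_trial_csv(path, markers_path=None, target: str = "C") -> TrialRecord:
    """Read one trial; the reference column is optional."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time", "eog_uv"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    time = df["time"].to_numpy(dtype=float)
    fs = _infer_fs(time, path)
    eog = TimeSeries(df["eog_uv"].to_numpy(dtype=float), fs,
                     unit="microvolt", t0=float(time[0]))
    reference = None
    if "ref_deg" in df.columns:
        reference = TimeSeries(df["ref_deg"].to_numpy(dtype=float), fs,
                               unit="degree", t0=float(time[0]))
    markers = read_markers_csv(markers_path) if markers_path else []
    return TrialRecord(eog=eog, markers=markers, target=target, reference=reference)


def write_trial_csv(path, trial: TrialRecord) -> None:
    cols = {"time": trial.eog.times, "eog_uv": trial.eog.values}
    if trial.reference is not None:
        cols["ref_deg"] = trial.reference.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def write_markers_csv(path, markers) -> None:
    pd.DataFrame({"time": [t for _, t in markers],
                  "label": [l for l, _ in markers]}).to_csv(path, index=False)


def write_signal_csv(path, signal: TimeSeries) -> None:
    pd.DataFrame({"time": signal.times, "value": signal.values}).to_csv(
        path, index=False, float_format="%.9g")


def read_signal_csv(path) -> TimeSeries:
    df = pd.read_csv(path, comment="#")
    for col in ("time", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    time = df["time"].to_numpy(dtype=float)
    fs = _infer_fs(time, path)
    return TimeSeries(df["value"].to_numpy(dtype=float), fs,
                      unit="dimensionless", t0=float(time[0]))


def save_calibration(path, cal: CalibrationModel) -> None:
    """Serialize a calibration model to a small JSON text file."""
    Path(path).write_text(json.dumps({
        "K": cal.K, "intercept": cal.intercept,
        "per_target_peak_averages": cal.per_target_peak_averages,
        "r_squared": cal.r_squared,
    }, indent=2))


def load_calibration(path) -> CalibrationModel:
    d = json.loads(Path(path).read_text())
    return CalibrationModel(K=d["K"], intercept=d["intercept"],
                            per_target_peak_averages=d.get("per_target_peak_averages", {}),
                            r_squared=d.get("r_squared", float("nan")))
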