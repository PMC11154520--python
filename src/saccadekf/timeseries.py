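"""Uniformly sampled time series — the currency passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Allowed unit tags.
UNITS = ("microvolt", "degree", "dimensionless")


@dataclass
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    values : array-like
        Sample values; stored as a float64 1-D array.
    fs : float
        Sampling rate in Hz (> 0).
    unit : str
        One of ``microvolt``, ``degree``, ``dimensionless``.
    t0 : float
        Time of the first sample, seconds.
    """

    values: np.ndarray
    fs: float
    unit: str = "microvolt"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds), clipped to range."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.values.size - 1)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeSeries":
        """Copy carrying new values (and optionally a new unit)."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if unit is not None:
            out.unit = unit
        return out

    def slice_time(self, t_start: float, t_stop: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_stop] (inclusive of nearest samples)."""
        i0 = self.index_at(t_start)
        i1 = self.index_at(t_stop)
        if i1 < i0:
            raise ValueError("t_stop precedes t_start")
        return TimeSeries(self.values[i0 : i1 + 1], self.fs, self.unit, self.t0 + i0 / self.fs)

    def require_finite(self) -> None:
        """Raise with the first offending index if any sample is non-finite."""
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")
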