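"""Core containers for beat-to-beat and evenly sampled heart-rate data.

An :class:`RRSeries` holds the beat times and R-R intervals of one heart,
as extracted from an ECG.  An :class:`HRSeries` holds instantaneous heart
rate resampled on an even time grid, together with a per-sample validity
mask (invalid samples arise from gaps before the first beat, after the
last beat, or from discarded low-quality segments) and, once low-pass
filtered, the time scale ``tau`` at which it was filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RRSeries", "HRSeries", "read_rr_csv", "write_rr_csv", "write_hr_csv"]

_RR_TOL = 1e-9  # allowed mismatch between intervals and diff(beat_times), s


@dataclass(frozen=True)
class RRSeries:
    """Beat times and R-R intervals of a single heart.

    Parameters
    ----------
    beat_times : ndarray of float
        Times of the detected R peaks in seconds, strictly increasing.
    intervals : ndarray of float
        R-R intervals in seconds; ``intervals[i]`` must equal
        ``beat_times[i+1] - beat_times[i]``.
    """

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        if bt.ndim != 1 or iv.ndim != 1 or len(iv) != len(bt) - 1:
            raise ValueError("need n beat times and n-1 intervals")
        if len(bt) < 2:
            raise ValueError("an RR series needs at least two beats")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(iv <= 0):
            raise ValueError("all RR intervals must be positive")
        if np.max(np.abs(np.diff(bt) - iv)) > _RR_TOL:
            raise ValueError("intervals inconsistent with beat times")

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray) -> "RRSeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(beat_times=bt, intervals=np.diff(bt))

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def mean_hr(self) -> float:
        """Mean heart rate in bpm (60 / mean RR)."""
        return 60.0 / float(np.mean(self.intervals))


@dataclass(frozen=True)
class HRSeries:
    """Evenly sampled instantaneous heart rate with a validity mask.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of sample 0 in seconds; sample k sits at ``t0 + k / fs``.
    values : ndarray of float
        Heart rate in bpm; finite wherever ``valid`` is True.
    valid : ndarray of bool
        Per-sample validity mask.
    tau : float or None
        Moving-average time scale in seconds if the series has been
        low-pass filtered, ``None`` for the raw (unfiltered) series.
    """

    fs: float
    t0: float
    values: np.ndarray
    valid: np.ndarray
    tau: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", m)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if v.shape != m.shape or v.ndim != 1:
            raise ValueError("values and valid must be 1-d arrays of equal length")
        if np.any(~np.isfinite(v[m])):
            raise ValueError("values must be finite where valid")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def with_mask(self, valid: np.ndarray) -> "HRSeries":
        return replace(self, valid=np.asarray(valid, dtype=bool))

    def valid_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of valid samples as (start, length) pairs."""
        return _bool_runs(self.valid)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# CSV interchange


def read_rr_csv(path: str | Path) -> RRSeries:
    """Read an RR series from a CSV with columns ``beat_time_s, rr_s``."""
    df = pd.read_csv(path)
    if not {"beat_time_s", "rr_s"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns beat_time_s, rr_s")
    bt = df["beat_time_s"].to_numpy(dtype=float)
    # Rebuild the final beat from the last interval so n times / n-1 intervals.
    rr = df["rr_s"].to_numpy(dtype=float)
    if len(bt) >= 2 and np.max(np.abs(np.diff(bt) - rr[:-1])) < _RR_TOL:
        times = bt
        intervals = rr[:-1]
    else:  # beat_time column marks interval starts only
        times = np.concatenate([bt, [bt[-1] + rr[-1]]])
        intervals = rr
    return RRSeries(beat_times=times, intervals=intervals)


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    """Write ``beat_time_s, rr_s`` rows; the last row repeats the final interval."""
    rr_col = np.concatenate([rr.intervals, [rr.intervals[-1]]])
    pd.DataFrame({"beat_time_s": rr.beat_times, "rr_s": rr_col}).to_csv(
        path, index=False
    )


def write_hr_csv(hr: HRSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"t_s": hr.times, "hr_bpm": hr.values, "valid": hr.valid.astype(int)}
    ).to_csv(path, index=False)
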