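"""RR-to-HR conversion, multiscale low-pass filtering and quality control.

The analysis pipeline works on instantaneous heart rate sampled on an even
grid (default 20 Hz).  Conversion from beat-to-beat data uses a zero-order
hold: HR(t) = 60 / RRI of the interval containing t, which matches the
piece-wise-constant character of raw heart rate.  Time-scale-dependent
filtering is a centered moving average of window ``round(tau * fs)``
samples; an output sample is valid only when its whole window is valid, so
filtering never manufactures data inside gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import HRSeries, RRSeries, _bool_runs

__all__ = [
    "FilterSpec",
    "rr_to_hr",
    "moving_average",
    "apply_quality_mask",
    "dyad_exclusion",
    "ExclusionDecision",
]


@dataclass(frozen=True)
class FilterSpec:
    """Moving-average filter at time scale ``tau`` for sampling rate ``fs``."""

    tau: float
    fs: float

    @property
    def window_samples(self) -> int:
        w = int(round(self.tau * self.fs))
        if w < 1:
            raise ValueError(
                f"window shorter than one sample: tau={self.tau}, fs={self.fs}"
            )
        return w


def rr_to_hr(rr: RRSeries, fs: float, duration: float | None = None) -> HRSeries:
    """Resample an RR series to instantaneous HR on an even grid.

    Zero-order hold: sample k at time ``t = k / fs`` takes the value
    ``60 / RRI`` of the beat-to-beat interval containing t.  Samples before
    the first beat or at/after the last beat are marked invalid.

    Parameters
    ----------
    rr : RRSeries
    fs : float
        Target sampling rate, Hz.
    duration : float, optional
        Length of the output grid in seconds (defaults to the last beat
        time), allowing several series to share one grid.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if rr.n_beats < 2:
        raise ValueError("need at least two beats")
    if duration is None:
        duration = float(rr.beat_times[-1])
    n = int(np.floor(duration * fs))
    t = np.arange(n) / fs
    # index of the interval containing t: searchsorted over beat starts
    idx = np.searchsorted(rr.beat_times, t, side="right") - 1
    inside = (idx >= 0) & (idx < len(rr.intervals))
    values = np.full(n, np.nan)
    values[inside] = 60.0 / rr.intervals[idx[inside]]
    return HRSeries(fs=fs, t0=0.0, values=values, valid=inside, tau=None)


def moving_average(hr: HRSeries, tau: float) -> HRSeries:
    """Centered moving average of window ``round(tau * fs)`` samples.

    The average runs over valid runs only; an output sample is valid iff
    the full window lies inside the input's valid samples.  The window is
    centered: for window w, sample k averages samples
    ``[k - (w-1)//2, k - (w-1)//2 + w)``.
    """
    if hr.tau is not None:
        raise ValueError("input is already filtered; filter the raw series")
    spec = FilterSpec(tau=tau, fs=hr.fs)
    w = spec.window_samples
    x = np.where(hr.valid, hr.values, 0.0)
    kernel = np.ones(w)
    sums = np.convolve(x, kernel, mode="full")
    counts = np.convolve(hr.valid.astype(float), kernel, mode="full")
    # full-convolution index j sums input samples [j-w+1, j]; align so that
    # output k covers the centered window [k-left, k-left+w)
    left = (w - 1) // 2
    start = w - 1 - left
    n = len(hr)
    sums = sums[start : start + n]
    counts = counts[start : start + n]
    valid = counts >= w - 0.5  # exact w up to float noise
    values = np.full(n, np.nan)
    values[valid] = sums[valid] / w
    return HRSeries(fs=hr.fs, t0=hr.t0, values=values, valid=valid, tau=tau)


def apply_quality_mask(
    hr: HRSeries, mask: np.ndarray, min_run_s: float = 10.0
) -> HRSeries:
    """Invalidate samples falling in bad seconds of a per-second quality mask.

    ``mask[i]`` covers the second ``[i, i+1)``.  After masking, valid runs
    shorter than ``min_run_s`` seconds are also invalidated: heart-rate
    segments too short to embed are useless downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    n_seconds_needed = int(np.ceil(len(hr) / hr.fs - 1e-9))
    if len(mask) < n_seconds_needed:
        raise ValueError(
            f"quality mask covers {len(mask)} s but recording spans "
            f"{n_seconds_needed} s"
        )
    second_of_sample = np.floor(hr.times).astype(int)
    second_of_sample = np.clip(second_of_sample, 0, len(mask) - 1)
    valid = hr.valid & mask[second_of_sample]
    min_run = int(np.ceil(min_run_s * hr.fs))
    for start, length in _bool_runs(valid):
        if length < min_run:
            valid[start : start + length] = False
    return hr.with_mask(valid)


@dataclass(frozen=True)
class ExclusionDecision:
    excluded: bool
    low_fhr_fraction: float
    threshold: float
    n_valid: int


def dyad_exclusion(
    fhr: HRSeries,
    mhr: HRSeries,
    max_low_fraction: float = 0.05,
    low_bpm: float = 100.0,
) -> ExclusionDecision:
    """Flag dyads whose fetal HR sits in the maternal range too often.

    When the fetal extraction locks onto the maternal heart, fHR drops to
    maternal values (< 100 bpm) for long stretches; such recordings carry
    no usable fetal signal.  The dyad is excluded when the fraction of
    valid fHR samples below ``low_bpm`` exceeds ``max_low_fraction``.
    """
    if fhr.fs != mhr.fs or len(fhr) != len(mhr):
        raise ValueError("fetal and maternal series must share one grid")
    n_valid = fhr.n_valid
    if n_valid == 0:
        raise ValueError("no valid fetal samples")
    frac = float(np.count_nonzero(fhr.values[fhr.valid] < low_bpm) / n_valid)
    return ExclusionDecision(
        excluded=frac > max_low_fraction,
        low_fhr_fraction=frac,
        threshold=max_low_fraction,
        n_valid=n_valid,
    )
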