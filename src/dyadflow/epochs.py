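"""Acceleration / deceleration epochs of a filtered heart-rate series.

Epochs are defined per time scale from the sign of the first difference of
the tau-filtered signal: a positive difference marks an acceleration
sample, a negative one a deceleration, and a difference within the (by
default zero) threshold band marks "neither".  Maximal runs of same-label
samples form events.  Because the derivative leaves a third category
(exact ties and run endpoints), the accel and decel time-point fractions
do not in general sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import HRSeries, _bool_runs

__all__ = ["EpochMask", "EpochStats", "label_epochs", "epoch_stats", "LABELS"]

# integer label codes
ACCEL, DECEL, NEITHER, INVALID = 1, -1, 0, -2
LABELS = {"accel": ACCEL, "decel": DECEL, "neither": NEITHER, "invalid": INVALID}
_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class EpochMask:
    """Per-sample accel/decel/neither labels at one time scale.

    ``labels`` uses the integer codes of :data:`LABELS`; ``events`` maps
    each label name to a list of maximal (start_index, length) runs.
    """

    tau: float
    fs: float
    labels: np.ndarray
    events: dict[str, list[tuple[int, int]]]

    def event_ids(self, label: str) -> np.ndarray:
        """Per-sample event index for one label (-1 outside such events).

        Used by conditioned estimators to keep embedding windows inside a
        single event.
        """
        out = np.full(len(self.labels), -1, dtype=np.int64)
        for i, (start, length) in enumerate(self.events[label]):
            out[start : start + length] = i
        return out

    def n_events(self, label: str) -> int:
        return len(self.events[label])


@dataclass(frozen=True)
class EpochStats:
    n_accel: int
    n_decel: int
    accel_fraction_events: float
    decel_fraction_events: float
    accel_fraction_time: float
    decel_fraction_time: float
    decel_accel_ratio: float
    ratio_defined: bool


def label_epochs(filtered: HRSeries, mu: float = 0.0) -> EpochMask:
    """Label each sample accel/decel/neither from the filtered-HR derivative.

    The derivative is the forward first difference ``d[k] = x[k+1] - x[k]``
    within each valid run; ``d > mu`` labels accel, ``d < -mu`` decel and
    ``|d| <= mu`` neither.  The last sample of each valid run, having no
    forward difference, is labeled neither.  Invalid samples keep the
    invalid label.

    Parameters
    ----------
    filtered : HRSeries
        Series filtered at the scale of interest (raw series are accepted;
        the recorded tau is then 1/fs).
    mu : float
        Derivative threshold in bpm per sample step; 0 by default so every
        non-tied sample is assigned.
    """
    if filtered.n_valid == 0:
        raise ValueError("all-invalid input")
    n = len(filtered)
    labels = np.full(n, INVALID, dtype=np.int8)
    for start, length in _bool_runs(filtered.valid):
        run = filtered.values[start : start + length]
        labels[start : start + length] = NEITHER
        if length < 2:
            continue
        d = np.diff(run)
        seg = labels[start : start + length - 1]
        seg[d > mu] = ACCEL
        seg[d < -mu] = DECEL
    events = {
        name: _label_runs(labels, code)
        for name, code in LABELS.items()
        if name != "invalid"
    }
    tau = filtered.tau if filtered.tau is not None else 1.0 / filtered.fs
    return EpochMask(tau=tau, fs=filtered.fs, labels=labels, events=events)


def _label_runs(labels: np.ndarray, code: int) -> list[tuple[int, int]]:
    return _bool_runs(labels == code)


def epoch_stats(mask: EpochMask) -> EpochStats:
    """Event counts and accel/decel fractions for one epoch mask.

    Both conventions are reported: event fractions (counts of maximal
    events) and time-point fractions (counts of labeled samples over all
    valid samples).  The decel/accel ratio uses event counts and is
    flagged undefined when there are no acceleration events.
    """
    n_accel = mask.n_events("accel")
    n_decel = mask.n_events("decel")
    n_events = n_accel + n_decel
    if n_events > 0:
        ev_acc = n_accel / n_events
        ev_dec = n_decel / n_events
    else:
        ev_acc = ev_dec = np.nan
    n_valid = int(np.count_nonzero(mask.labels != INVALID))
    if n_valid > 0:
        t_acc = float(np.count_nonzero(mask.labels == ACCEL) / n_valid)
        t_dec = float(np.count_nonzero(mask.labels == DECEL) / n_valid)
    else:
        t_acc = t_dec = np.nan
    defined = n_accel > 0
    ratio = n_decel / n_accel if defined else np.nan
    return EpochStats(
        n_accel=n_accel,
        n_decel=n_decel,
        accel_fraction_events=ev_acc,
        decel_fraction_events=ev_dec,
        accel_fraction_time=t_acc,
        decel_fraction_time=t_dec,
        decel_accel_ratio=ratio,
        ratio_defined=defined,
    )
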