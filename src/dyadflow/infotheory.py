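"""Multiscale entropy rate, sample entropy and transfer entropy.

All estimators work on the tau-filtered heart-rate series and use the
filter scale both as the low-pass window and as the embedding lag, so a
single parameter tau selects the time scale under study.  Differential
entropies use the Kozachenko–Leonenko k-nearest-neighbor estimator and
transfer entropy the Kraskov–Stögbauer–Grassberger (KSG) conditional
mutual-information scheme, both with the Chebyshev norm and k = 5 by
default.  Raw transfer entropies are bias-corrected by subtracting the
mean estimate over circular time shifts of the source, which preserve
both marginals and the destination's autocorrelation while destroying any
cross-coupling.

Event conditioning restricts estimation to embedding vectors whose entire
window (past and future samples) lies inside a single acceleration or
deceleration event of the conditioning signal; this prevents leakage
across regime boundaries.  Five paradigms are supported: no conditioning,
and accelerations/decelerations of either the maternal or the fetal heart
rate.  Reducing every metric curve to its maximum and mean over the vagal
band [0.5, 2.5] s yields 50 features per dyad
(2 metrics x 2 signals x 5 paradigms x 2 summaries for the univariate
entropies, plus net TE x 5 paradigms x 2 summaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import digamma
from sklearn.neighbors import KDTree

from .epochs import EpochMask, label_epochs
from .preprocess import apply_quality_mask, moving_average, rr_to_hr
from .series import HRSeries

__all__ = [
    "EntropyParams",
    "ScaleGrid",
    "Estimate",
    "PreparedDyad",
    "PARADIGMS",
    "knn_entropy",
    "entropy_rate",
    "sample_entropy",
    "transfer_entropy",
    "surrogate_correction",
    "net_transfer_entropy",
    "compute_features",
    "feature_names",
    "FeatureResult",
]

PARADIGMS = ("none", "mhr_accel", "mhr_decel", "fhr_accel", "fhr_decel")


class Estimate(NamedTuple):
    """A point estimate in nats with its usable-vector count.

    ``value`` is NaN when the estimate is missing; ``reason`` then says why.
    """

    value: float
    n: int
    reason: str | None = None


@dataclass(frozen=True)
class EntropyParams:
    """Estimator settings shared by all information metrics.

    ``max_vectors`` caps the number of embedding vectors per estimate (a
    random subsample, seeded) to bound k-NN search cost; ``min_vectors``
    is the floor below which estimates are reported missing because k-NN
    estimates are variance-dominated.
    """

    k_neighbors: int = 5
    sampen_m: int = 1
    sampen_r_factor: float = 0.2  # times the SD of the analyzed sample set
    n_surrogates: int = 20
    seed: int = 0
    min_vectors: int = 100
    max_vectors: int = 4000
    jitter_scale: float = 1e-6  # times the column SD, breaks quantization ties
    # embedding vectors are taken every stride_fraction * lag samples:
    # successive vectors of a tau-smoothed signal are near-duplicates, and
    # feeding them all to a k-NN estimator biases entropies low (nearest
    # neighbors become temporal neighbors)
    stride_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.sampen_r_factor <= 0:
            raise ValueError("sampen_r_factor must be positive")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


@dataclass(frozen=True)
class ScaleGrid:
    """Time scales tau (s) and the summary band for feature reduction."""

    taus: tuple[float, ...]
    summary_interval: tuple[float, float] = (0.5, 2.5)

    def __post_init__(self) -> None:
        t = np.asarray(self.taus, dtype=float)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("taus must be strictly increasing and non-empty")

    @classmethod
    def default(cls, fs: float = 20.0) -> "ScaleGrid":
        """Log-spaced band coverage from 1/fs up to 20 s.

        Six points inside the vagal summary band [0.5, 2.5] s plus coarse
        coverage below and above it.
        """
        below = [1.0 / fs, 0.1, 0.2, 0.35]
        band = list(np.round(np.geomspace(0.5, 2.5, 6), 4))
        above = [5.0, 10.0, 20.0]
        taus = tuple(sorted(set(t for t in below + band + above if t >= 1.0 / fs)))
        return cls(taus=taus)

    def in_band(self, taus=None) -> np.ndarray:
        t = np.asarray(self.taus if taus is None else taus, dtype=float)
        lo, hi = self.summary_interval
        return (t >= lo - 1e-12) & (t <= hi + 1e-12)


# ---------------------------------------------------------------------------
# base estimators


def _jitter_columns(cols: np.ndarray, rng: np.random.Generator, scale: float):
    """Additive uniform jitter per column to break quantization ties."""
    out = np.array(cols, dtype=float, copy=True)
    for j in range(out.shape[1]):
        sd = float(np.std(out[:, j]))
        if sd == 0:
            warnings.warn("zero-variance embedding dimension; jittering anyway")
            sd = 1.0
        a = scale * sd
        out[:, j] += rng.uniform(-a, a, size=out.shape[0])
    return out


def knn_entropy(
    points: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
    jitter_scale: float = 1e-6,
) -> float:
    """Kozachenko–Leonenko differential entropy in nats (Chebyshev norm).

    H = psi(n) - psi(k) + d log 2 + (d/n) sum_i log eps_i, with eps_i the
    distance from point i to its k-th nearest neighbor.  Duplicate points
    are broken by a seeded uniform jitter of ``jitter_scale`` times each
    column's SD.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    if rng is None:
        rng = np.random.default_rng(0)
    pts = _jitter_columns(pts, rng, jitter_scale)
    tree = KDTree(pts, metric="chebyshev")
    dist = tree.query(pts, k=k + 1)[0][:, -1]
    dist = np.maximum(dist, 1e-300)
    return float(digamma(n) - digamma(k) + d * np.log(2.0) + d * np.mean(np.log(dist)))


def _ksg_cmi(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    k: int,
    rng: np.random.Generator,
    jitter_scale: float = 1e-6,
) -> float:
    """KSG (algorithm 1) conditional mutual information I(x; y | z) in nats."""
    cols = _jitter_columns(np.column_stack([x, y, z]), rng, jitter_scale)
    xj, yj, zj = cols[:, [0]], cols[:, [1]], cols[:, [2]]
    joint = cols
    tree = KDTree(joint, metric="chebyshev")
    eps = tree.query(joint, k=k + 1)[0][:, -1]
    # strictly-inside counts per KSG; shave the radius below eps
    r = eps * (1.0 - 1e-10)
    n_xz = KDTree(np.column_stack([xj, zj]), metric="chebyshev").query_radius(
        np.column_stack([xj, zj]), r, count_only=True
    ) - 1
    n_yz = KDTree(np.column_stack([yj, zj]), metric="chebyshev").query_radius(
        np.column_stack([yj, zj]), r, count_only=True
    ) - 1
    n_z = KDTree(zj, metric="chebyshev").query_radius(zj, r, count_only=True) - 1
    return float(
        digamma(k)
        - np.mean(digamma(n_xz + 1) + digamma(n_yz + 1) - digamma(n_z + 1))
    )


# ---------------------------------------------------------------------------
# embedding-vector selection


def _lag_samples(series: HRSeries) -> int:
    if series.tau is None:
        raise ValueError("series must be filtered at some scale tau")
    lag = int(round(series.tau * series.fs))
    if lag < 1:
        raise ValueError("tau below one sample period")
    return lag


def _resolve_condition(condition) -> tuple[np.ndarray | None, str | None]:
    """Accept (EpochMask, label) or None; return per-sample event ids."""
    if condition is None:
        return None, None
    mask, label = condition
    if not isinstance(mask, EpochMask):
        raise TypeError("condition must be an (EpochMask, label) pair")
    return mask.event_ids(label), label


def _embedding_bases(
    valids: list[tuple[np.ndarray, int]],
    n: int,
    event_ids: np.ndarray | None,
    event_offsets: list[int],
) -> np.ndarray:
    """Base indices whose embedding window is fully valid (and in-event).

    ``valids`` pairs a validity mask with the offset at which it must hold;
    ``event_offsets`` lists the offsets that must share one event of the
    conditioning mask.
    """
    max_off = max(off for _, off in valids)
    if n <= max_off:
        return np.empty(0, dtype=np.int64)
    base = np.arange(n - max_off)
    ok = np.ones(len(base), dtype=bool)
    for mask, off in valids:
        ok &= mask[base + off]
    if event_ids is not None:
        e0 = event_ids[base + event_offsets[0]]
        ok &= e0 >= 0
        for off in event_offsets[1:]:
            ok &= event_ids[base + off] == e0
    return base[ok]


def _subsample(idx: np.ndarray, max_n: int, rng: np.random.Generator) -> np.ndarray:
    if len(idx) <= max_n:
        return idx
    return np.sort(rng.choice(idx, size=max_n, replace=False))


def _stride(bases: np.ndarray, lag: int, params: EntropyParams) -> np.ndarray:
    step = max(1, int(round(lag * params.stride_fraction)))
    return bases[::step]


# ---------------------------------------------------------------------------
# metric estimators on filtered series


def entropy_rate(
    x: HRSeries, params: EntropyParams | None = None, condition=None
) -> Estimate:
    """Entropy rate h(tau) = H(x_t, x_{t+L}) - H(x_t), L = round(tau fs).

    The conditional entropy of the signal one scale step ahead given its
    present, i.e. the rate of new information generation at scale tau.
    Conditioning restricts the (x_t, x_{t+L}) pairs to windows inside one
    epoch of the required type.
    """
    params = params or EntropyParams()
    lag = _lag_samples(x)
    event_ids, _ = _resolve_condition(condition)
    bases = _embedding_bases(
        [(x.valid, 0), (x.valid, lag)], len(x), event_ids, [0, lag]
    )
    bases = _stride(bases, lag, params)
    rng = np.random.default_rng(params.seed)
    bases = _subsample(bases, params.max_vectors, rng)
    if len(bases) < max(params.min_vectors, params.k_neighbors + 1):
        return Estimate(np.nan, len(bases), "insufficient embedding pairs")
    joint = np.column_stack([x.values[bases], x.values[bases + lag]])
    h2 = knn_entropy(joint, params.k_neighbors, rng, params.jitter_scale)
    h1 = knn_entropy(joint[:, :1], params.k_neighbors, rng, params.jitter_scale)
    return Estimate(h2 - h1, len(bases))


def sample_entropy(
    x: HRSeries, params: EntropyParams | None = None, condition=None
) -> Estimate:
    """Sample entropy -ln(A/B) with Chebyshev distance and no self-matches.

    B counts template pairs of length m within tolerance
    r = r_factor * SD(analyzed samples); A counts the same for length
    m + 1.  Template elements are spaced by the scale lag
    L = round(tau fs) (the multiscale convention: consecutive samples of
    the smoothed signal carry no new information), and templates never
    span invalid samples or epoch boundaries.
    """
    params = params or EntropyParams()
    m = params.sampen_m
    lag = _lag_samples(x)
    offsets = [i * lag for i in range(m + 1)]
    event_ids, _ = _resolve_condition(condition)
    bases = _embedding_bases(
        [(x.valid, off) for off in offsets], len(x), event_ids, offsets
    )
    bases = _stride(bases, lag, params)
    rng = np.random.default_rng(params.seed)
    bases = _subsample(bases, params.max_vectors, rng)
    if len(bases) < max(params.min_vectors, 2):
        return Estimate(np.nan, len(bases), "insufficient templates")
    used = np.unique(bases[:, None] + np.asarray(offsets)[None, :])
    r = params.sampen_r_factor * float(np.std(x.values[used]))
    if r <= 0:
        # constant segment: every template matches every other
        return Estimate(0.0, len(bases))
    tm = np.column_stack([x.values[bases + off] for off in offsets[:-1]])
    tm1 = np.column_stack([x.values[bases + off] for off in offsets])
    b_count = _match_pairs(tm, r)
    if b_count == 0:
        return Estimate(np.nan, len(bases), "no m-template matches")
    a_count = _match_pairs(tm1, r)
    if a_count == 0:
        return Estimate(np.nan, len(bases), "no (m+1)-template matches")
    return Estimate(float(-np.log(a_count / b_count)), len(bases))


def _match_pairs(templates: np.ndarray, r: float) -> int:
    """Unordered template pairs within Chebyshev distance r (self excluded)."""
    tree = KDTree(templates, metric="chebyshev")
    counts = tree.query_radius(templates, r, count_only=True)
    return int((counts.sum() - len(templates)) // 2)


def transfer_entropy(
    src: HRSeries,
    dst: HRSeries,
    params: EntropyParams | None = None,
    condition=None,
    _src_shift: int = 0,
) -> Estimate:
    """Raw transfer entropy TE_src->dst(tau) = I(dst_{t+L}; src_t | dst_t).

    Estimated with the KSG conditional-mutual-information k-NN scheme; the
    embedding uses a single past lag for each signal and a future horizon
    of L = round(tau fs) samples, tau being the shared filter scale.
    ``_src_shift`` circularly rotates the source values *within its valid
    samples* (used internally to build surrogates): the validity pattern —
    and therefore the embedding-base set — is exactly that of the raw
    estimate, so the surrogate ensemble shares its finite-sample bias.
    """
    params = params or EntropyParams()
    if src.fs != dst.fs or len(src) != len(dst):
        raise ValueError("source and destination must share one grid")
    if src.tau != dst.tau:
        raise ValueError("source and destination must be filtered at the same tau")
    lag = _lag_samples(dst)
    src_vals = src.values
    src_valid = src.valid
    if _src_shift:
        vi = np.flatnonzero(src.valid)
        src_vals = np.array(src.values, copy=True)
        src_vals[vi] = src.values[vi[(np.arange(len(vi)) - _src_shift) % len(vi)]]
    event_ids, _ = _resolve_condition(condition)
    bases = _embedding_bases(
        [(dst.valid, 0), (dst.valid, lag), (src_valid, 0)],
        len(dst),
        event_ids,
        [0, lag],
    )
    bases = _stride(bases, lag, params)
    rng = np.random.default_rng(params.seed)
    bases = _subsample(bases, params.max_vectors, rng)
    if len(bases) < max(params.min_vectors, params.k_neighbors + 1):
        return Estimate(np.nan, len(bases), "insufficient embedding vectors")
    cmi = _ksg_cmi(
        src_vals[bases],
        dst.values[bases + lag],
        dst.values[bases],
        params.k_neighbors,
        rng,
        params.jitter_scale,
    )
    return Estimate(cmi, len(bases))


def surrogate_correction(
    src: HRSeries,
    dst: HRSeries,
    params: EntropyParams | None = None,
    condition=None,
) -> Estimate:
    """Bias-corrected TE: raw minus the mean over source time-shift surrogates.

    Each surrogate circularly shifts the source by a random offset of at
    least ten embedding lags (and at most n minus that), destroying the
    cross-coupling while preserving the marginals and the destination's
    own dynamics.
    """
    params = params or EntropyParams()
    raw = transfer_entropy(src, dst, params, condition)
    if not np.isfinite(raw.value):
        return raw
    lag = _lag_samples(dst)
    n = src.n_valid
    min_shift = 10 * lag
    if 2 * min_shift >= n:
        min_shift = max(lag, n // 8)
    rng = np.random.default_rng(params.seed + 1)
    shifts = rng.integers(min_shift, n - min_shift, size=params.n_surrogates)
    null = [
        transfer_entropy(src, dst, params, condition, _src_shift=int(s)).value
        for s in shifts
    ]
    null = [v for v in null if np.isfinite(v)]
    if not null:
        return Estimate(np.nan, raw.n, "all surrogates missing")
    return Estimate(raw.value - float(np.mean(null)), raw.n)


def net_transfer_entropy(
    mhr: HRSeries,
    fhr: HRSeries,
    params: EntropyParams | None = None,
    condition=None,
) -> tuple[Estimate, Estimate, Estimate]:
    """Corrected TE in both directions and their difference.

    Returns ``(te_mf, te_fm, net)`` with ``net = TE_m->f - TE_f->m``;
    positive net values indicate net maternal-to-fetal information flow.
    """
    te_mf = surrogate_correction(mhr, fhr, params, condition)
    te_fm = surrogate_correction(fhr, mhr, params, condition)
    if not (np.isfinite(te_mf.value) and np.isfinite(te_fm.value)):
        return te_mf, te_fm, Estimate(np.nan, 0, "a direction is missing")
    n = min(te_mf.n, te_fm.n)
    return te_mf, te_fm, Estimate(te_mf.value - te_fm.value, n)


# ---------------------------------------------------------------------------
# per-dyad feature extraction


@dataclass(frozen=True)
class PreparedDyad:
    """Raw maternal and fetal HR series on a shared even grid."""

    mhr: HRSeries
    fhr: HRSeries
    dyad_id: str = "dyad"

    @classmethod
    def from_recording(
        cls, recording, fs: float = 20.0, min_run_s: float = 10.0
    ) -> "PreparedDyad":
        """Resample both RR series of a recording and apply its quality mask."""
        duration = min(
            recording.maternal_rr.beat_times[-1], recording.fetal_rr.beat_times[-1]
        )
        mhr = rr_to_hr(recording.maternal_rr, fs, duration)
        fhr = rr_to_hr(recording.fetal_rr, fs, duration)
        mask = recording.quality_mask
        mhr = apply_quality_mask(mhr, mask, min_run_s)
        fhr = apply_quality_mask(fhr, mask, min_run_s)
        return cls(mhr=mhr, fhr=fhr, dyad_id=recording.dyad_id)


def feature_names() -> list[str]:
    """The 50 feature names: {er,se} x {mhr,fhr} x paradigms x {max,auc}
    plus net_te x paradigms x {max,auc}."""
    names = []
    for metric in ("er", "se"):
        for signal in ("mhr", "fhr"):
            for paradigm in PARADIGMS:
                for summary in ("max", "auc"):
                    names.append(f"{metric}_{signal}_{paradigm}_{summary}")
    for paradigm in PARADIGMS:
        for summary in ("max", "auc"):
            names.append(f"net_te_pair_{paradigm}_{summary}")
    return names


@dataclass(frozen=True)
class FeatureResult:
    """Per-dyad feature vector plus the metric curves behind it."""

    dyad_id: str
    features: dict[str, float]
    curves: pd.DataFrame
    missing: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"dyad_id": self.dyad_id, **self.features}])


def _condition_for(paradigm: str, masks: dict[str, EpochMask]):
    if paradigm == "none":
        return None
    signal, label = paradigm.split("_")
    return masks[signal], label


def _summarize(taus, values, grid: ScaleGrid, auc_mode: str = "mean"):
    """Max and band-mean of a curve over the summary-interval grid points."""
    taus = np.asarray(taus, dtype=float)
    values = np.asarray(values, dtype=float)
    band = grid.in_band(taus) & np.isfinite(values)
    if not band.any():
        return np.nan, np.nan
    v, t = values[band], taus[band]
    vmax = float(np.max(v))
    if auc_mode == "trapezoid" and len(t) > 1:
        auc = float(np.trapezoid(v, t) / (t[-1] - t[0]))
    else:
        auc = float(np.mean(v))
    return vmax, auc


def compute_features(
    prep: PreparedDyad,
    grid: ScaleGrid | None = None,
    params: EntropyParams | None = None,
    te_full_grid: bool = False,
    auc_mode: str = "mean",
) -> FeatureResult:
    """Compute all metric curves and reduce them to the 50-feature vector.

    ER and SE curves run over the whole scale grid; transfer entropy,
    whose surrogate ensemble dominates compute cost, is evaluated on the
    summary-band grid points only unless ``te_full_grid`` is set (the
    feature reduction uses only those points either way).

    Missing estimates propagate: a feature whose curve has no finite
    in-band point is NaN and listed in ``missing``.
    """
    params = params or EntropyParams()
    grid = grid or ScaleGrid.default(prep.mhr.fs)
    rows = []
    for tau in grid.taus:
        if int(round(tau * prep.mhr.fs)) < 1:
            continue
        filtered = {
            "mhr": moving_average(prep.mhr, tau),
            "fhr": moving_average(prep.fhr, tau),
        }
        masks = {sig: label_epochs(f) for sig, f in filtered.items()}
        do_te = te_full_grid or bool(grid.in_band([tau])[0])
        for paradigm in PARADIGMS:
            condition = _condition_for(paradigm, masks)
            for signal in ("mhr", "fhr"):
                er = entropy_rate(filtered[signal], params, condition)
                se = sample_entropy(filtered[signal], params, condition)
                rows.append(("er", signal, paradigm, tau, er.value, er.n))
                rows.append(("se", signal, paradigm, tau, se.value, se.n))
            if do_te:
                te_mf, te_fm, net = net_transfer_entropy(
                    filtered["mhr"], filtered["fhr"], params, condition
                )
                rows.append(("te_mf", "pair", paradigm, tau, te_mf.value, te_mf.n))
                rows.append(("te_fm", "pair", paradigm, tau, te_fm.value, te_fm.n))
                rows.append(("net_te", "pair", paradigm, tau, net.value, net.n))
    curves = pd.DataFrame(
        rows, columns=["metric", "signal", "paradigm", "tau_s", "value_nats", "n_points"]
    )
    features: dict[str, float] = {}
    missing: dict[str, str] = {}
    for name in feature_names():
        metric, signal, paradigm, summary = _parse_feature_name(name)
        sub = curves[
            (curves.metric == metric)
            & (curves.signal == signal)
            & (curves.paradigm == paradigm)
        ]
        vmax, auc = _summarize(sub.tau_s, sub.value_nats, grid, auc_mode)
        value = vmax if summary == "max" else auc
        features[name] = value
        if not np.isfinite(value):
            missing[name] = "no finite curve point in the summary band"
    return FeatureResult(
        dyad_id=prep.dyad_id, features=features, curves=curves, missing=missing
    )


def _parse_feature_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split("_")
    if parts[0] == "net":  # net_te_pair_{paradigm}_{summary}
        metric, signal = "net_te", "pair"
        paradigm = "_".join(parts[3:-1])
    else:
        metric, signal = parts[0], parts[1]
        paradigm = "_".join(parts[2:-1])
    return metric, signal, paradigm, parts[-1]
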