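"""Synthetic maternal–fetal dyad recordings and cohort tables.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without clinical recordings:

* each heart follows a continuous-time target heart rate built from a mean
  level (~80 bpm maternal, ~140 bpm fetal), a sum of sinusoidal oscillators
  (respiratory and Mayer-band for the mother, breathing-movement band for
  the fetus) and an AR(1) stochastic component;
* the fetal stochastic innovations receive an additive contribution from
  the maternal moving-average-filtered heart rate delayed by a lag
  ``coupling_lag`` and scaled by a DC gain ``coupling_gain`` — a purely
  maternal-to-fetal, time-lagged coupling;
* during ground-truth maternal decelerations (negative derivative of the
  smoothed maternal target rate) the fetal innovation variance is
  multiplied by ``decel_variance_factor``, emulating state-contingent
  quieting of fetal variability;
* beats are produced by integrate-and-fire on the cumulative phase of the
  target rate, then corrupted by an R-peak localization jitter of half an
  ECG sample and snapped to the ECG sampling grid (1/f_ecg), which bounds
  the per-interval timing error by 2/f_ecg;
* a per-second quality mask drops a configurable fraction of random
  seconds, standing in for low-signal-quality exclusions.

Cohort generation layers stress-group and fetal-sex structure on top: the
coupling gain carries a stress main effect and a sex-by-stress
interaction, hair cortisol is drawn with a prescribed correlation to the
gain, and neurodevelopmental outcomes are pure noise unless given an
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import RRSeries, write_rr_csv

__all__ = [
    "SimConfig",
    "DyadRecording",
    "EffectMap",
    "CohortSpec",
    "generate_dyad",
    "generate_cohort",
    "write_cohort",
    "rr_quantization_noise",
    "hr_noise_amplitude",
]

_INTERNAL_DT = 0.02  # s, internal simulation grid (50 Hz)
_TRUTH_SMOOTH_S = 2.5  # s, smoothing window defining ground-truth decelerations


def rr_quantization_noise(f_ecg: float) -> float:
    """R-R timing resolution 2 / f_ecg in seconds.

    Each R peak is localized to within one ECG sample, so an interval
    (two peaks) carries an error of up to two sample periods.
    """
    if f_ecg <= 0:
        raise ValueError("f_ecg must be positive")
    return 2.0 / f_ecg


def hr_noise_amplitude(mean_hr_bpm: float, delta_rri_s: float) -> float:
    """Heart-rate noise (bpm) propagated from an R-R timing error.

    With HR = 60 / RRI, a timing error ``delta_rri_s`` maps to
    ``dHR = 60 * dRRI / RRI**2 = HR**2 * dRRI / 60``.
    """
    return mean_hr_bpm**2 * delta_rri_s / 60.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dyad recording.

    Heart-rate levels and oscillator bands follow typical third-trimester
    physiology; the coupling gain is the steady-state bpm-per-bpm response
    of the fetal target rate to a sustained maternal deviation.
    """

    duration: float = 2400.0  # s; clinical recordings lasted >= 40 min
    maternal_mean_rr: float = 0.75  # s (~80 bpm)
    fetal_mean_rr: float = 0.43  # s (~140 bpm)
    # (frequency Hz, amplitude bpm): respiratory and Mayer bands for the
    # mother; breathing-movement and slow bands for the fetus
    maternal_oscillators: tuple[tuple[float, float], ...] = ((0.25, 1.8), (0.10, 3.0))
    fetal_oscillators: tuple[tuple[float, float], ...] = ((0.70, 1.2), (0.15, 2.4))
    maternal_innovation_sd: float = 1.5  # bpm, stationary SD of AR(1) part
    fetal_innovation_sd: float = 2.0  # bpm
    maternal_ar_time: float = 1.0  # s, AR(1) correlation time
    fetal_ar_time: float = 0.5  # s
    # negative skew of the AR(1) innovations: occasional sharp drops with
    # slower recoveries, giving the slight acceleration-time dominance seen
    # in real heart rate (stronger in the fetus)
    maternal_innovation_skew: float = -0.5
    fetal_innovation_skew: float = -1.5
    # waveform asymmetry of the oscillators (0 = sine): positive values
    # lengthen the rising flank relative to the falling one, the second
    # source of acceleration dominance
    maternal_oscillator_asymmetry: float = 0.1
    fetal_oscillator_asymmetry: float = 0.6
    # 1/f-like background: a bank of AR(1) components with log-spaced
    # correlation times carrying equal variance shares, reproducing the
    # low-frequency continuum of real heart-rate variability (without it
    # the signal has no information left at scales beyond the oscillators)
    maternal_background_sd: float = 4.0  # bpm, total SD of the bank
    fetal_background_sd: float = 4.0  # bpm
    background_times: tuple[float, ...] = (0.5, 1.5, 4.5, 13.5, 40.0, 120.0)  # s
    coupling_gain: float = 0.3  # dimensionless DC gain, >= 0
    coupling_lag: float = 1.0  # s, in the vagal band [0.5, 2.5]
    decel_variance_factor: float = 0.5  # rho in (0, 1]
    f_ecg: float = 1000.0  # Hz; beat times quantized to 1/f_ecg
    quantize: bool = True
    mask_drop_fraction: float = 0.05  # fraction of 1-s windows dropped
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.maternal_mean_rr <= 0 or self.fetal_mean_rr <= 0:
            raise ValueError("mean RR intervals must be positive")
        if self.coupling_gain < 0:
            raise ValueError("coupling gain must be >= 0")
        if self.coupling_lag < 0:
            raise ValueError("coupling lag must be >= 0")
        if not 0 < self.decel_variance_factor <= 1:
            raise ValueError("decel_variance_factor must be in (0, 1]")
        if self.f_ecg <= 0:
            raise ValueError("f_ecg must be positive")


@dataclass(frozen=True)
class DyadRecording:
    """One synthetic dyad: two RR series, a quality mask and its ground truth."""

    dyad_id: str
    maternal_rr: RRSeries
    fetal_rr: RRSeries
    quality_mask: np.ndarray  # per-second booleans, True = keep
    truth: SimConfig

    def __post_init__(self) -> None:
        expected = int(np.ceil(self.truth.duration))
        if len(self.quality_mask) != expected:
            raise ValueError("quality mask must cover ceil(duration) seconds")


def _skewed_noise(n: int, skew: float, rng) -> np.ndarray:
    """Zero-mean unit-SD noise with the requested skewness (gamma-based)."""
    if skew == 0:
        return rng.standard_normal(n)
    a = 4.0 / skew**2
    z = (rng.gamma(a, 1.0, size=n) - a) / np.sqrt(a)
    return z if skew > 0 else -z


def _ar1_path(
    n: int, dt: float, corr_time: float, stationary_sd: float, rng, inputs=None,
    step_sd_scale=None, skew: float = 0.0,
):
    """AR(1) sample path with optional exogenous input added to the innovations."""
    phi = float(np.exp(-dt / corr_time))
    step_sd = stationary_sd * np.sqrt(1.0 - phi**2)
    w = step_sd * _skewed_noise(n, skew, rng)
    if step_sd_scale is not None:
        w *= step_sd_scale
    if inputs is not None:
        w = w + inputs
    return lfilter([1.0], [1.0, -phi], w)


def _background_bank(
    n, dt, times, total_sd, rng, sd_scale=None, skew: float = 0.0
) -> np.ndarray:
    """1/f-like continuum: AR(1) bank with equal variance per octave-ish band."""
    if total_sd == 0 or not times:
        return np.zeros(n)
    sd_i = total_sd / np.sqrt(len(times))
    out = np.zeros(n)
    for corr_time in times:
        out += _ar1_path(
            n, dt, corr_time, sd_i, rng, step_sd_scale=sd_scale, skew=skew
        )
    return out


def _oscillator_sum(t, oscillators, rng, asymmetry: float = 0.0):
    """Sum of (phase-warped) sinusoids; asymmetry > 0 lengthens rising flanks."""
    out = np.zeros_like(t)
    for freq, amp in oscillators:
        phase = rng.uniform(0, 2 * np.pi)
        theta = 2 * np.pi * freq * t + phase
        out += amp * np.sin(theta - asymmetry * np.sin(theta))
    return out


def _integrate_and_fire(t, hr_bpm):
    """Beat times where the cumulative phase of rate HR/60 crosses integers."""
    rate = np.maximum(hr_bpm, 20.0) / 60.0  # beats/s, floored for safety
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))])
    n_beats = int(np.floor(phase[-1]))
    return np.interp(np.arange(1, n_beats + 1), phase, t)


def _quantize_beats(beat_times, f_ecg, rng):
    """Snap each beat to the ECG sampling grid by stochastic rounding.

    The detected R peak falls on one of the two ECG samples bracketing the
    true peak, so each beat time moves by strictly less than one sample and
    each interval by strictly less than two (the 2/f_ecg timing noise).
    """
    ticks = beat_times * f_ecg
    return np.floor(ticks + rng.uniform(0.0, 1.0, size=len(ticks))) / f_ecg


def generate_dyad(
    config: SimConfig, seed: int | None = None, dyad_id: str = "SIM-000"
) -> DyadRecording:
    """Simulate one maternal–fetal dyad recording.

    Parameters
    ----------
    config : SimConfig
    seed : int, optional
        Overrides ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dt = _INTERNAL_DT
    n = int(round(config.duration / dt)) + 1
    t = np.arange(n) * dt

    m_mean = 60.0 / config.maternal_mean_rr
    f_mean = 60.0 / config.fetal_mean_rr

    # maternal target HR
    m_osc = _oscillator_sum(
        t, config.maternal_oscillators, rng, config.maternal_oscillator_asymmetry
    )
    m_ar = _ar1_path(
        n, dt, config.maternal_ar_time, config.maternal_innovation_sd, rng,
        skew=config.maternal_innovation_skew,
    )
    m_bg = _background_bank(
        n, dt, config.background_times, config.maternal_background_sd, rng,
        skew=config.maternal_innovation_skew,
    )
    m_hr = m_mean + m_osc + m_ar + m_bg

    # ground-truth maternal state: sign of the derivative of the smoothed
    # maternal target rate (independent of any downstream estimator)
    w = max(int(round(_TRUTH_SMOOTH_S / dt)), 1)
    kernel = np.ones(w) / w
    m_smooth = np.convolve(m_hr, kernel, mode="same")
    decel_truth = np.gradient(m_smooth, dt) < 0

    # maternal drive seen by the fetus: moving-average over the lag window,
    # delayed by the coupling lag
    lag_steps = int(round(config.coupling_lag / dt))
    wlag = max(lag_steps, 1)
    m_filt = np.convolve(m_hr - m_mean, np.ones(wlag) / wlag, mode="same")
    m_drive = np.zeros(n)
    if lag_steps < n:
        m_drive[lag_steps:] = m_filt[: n - lag_steps]

    phi_f = float(np.exp(-dt / config.fetal_ar_time))
    gain_step = config.coupling_gain * (1.0 - phi_f) * m_drive
    sd_scale = np.where(decel_truth, np.sqrt(config.decel_variance_factor), 1.0)

    f_osc = _oscillator_sum(
        t, config.fetal_oscillators, rng, config.fetal_oscillator_asymmetry
    )
    f_ar = _ar1_path(
        n,
        dt,
        config.fetal_ar_time,
        config.fetal_innovation_sd,
        rng,
        inputs=gain_step,
        step_sd_scale=sd_scale,
        skew=config.fetal_innovation_skew,
    )
    f_bg = _background_bank(
        n, dt, config.background_times, config.fetal_background_sd, rng,
        sd_scale=sd_scale, skew=config.fetal_innovation_skew,
    )
    f_hr = f_mean + f_osc + f_ar + f_bg

    m_beats = _integrate_and_fire(t, m_hr)
    f_beats = _integrate_and_fire(t, f_hr)
    if config.quantize:
        m_beats = _quantize_beats(m_beats, config.f_ecg, rng)
        f_beats = _quantize_beats(f_beats, config.f_ecg, rng)

    n_seconds = int(np.ceil(config.duration))
    mask = np.ones(n_seconds, dtype=bool)
    n_drop = int(round(config.mask_drop_fraction * n_seconds))
    if n_drop > 0:
        mask[rng.choice(n_seconds, size=n_drop, replace=False)] = False

    cfg = replace(config, seed=seed)
    return DyadRecording(
        dyad_id=dyad_id,
        maternal_rr=RRSeries.from_beat_times(m_beats),
        fetal_rr=RRSeries.from_beat_times(f_beats),
        quality_mask=mask,
        truth=cfg,
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class EffectMap:
    """Cohort-level effect structure on the coupling gain and outcomes.

    These effect sizes are free choices of the simulator (the clinical
    study reports model coefficients on entropy features, not generative
    gains); signs follow the reported direction: stress raises the
    temporal-coupling measure overall while stressed male fetuses fall
    below the additive expectation.
    """

    c_base: float = 0.3
    c_sd: float = 0.08  # between-dyad SD of the gain
    stress_effect: float = 0.06  # added to c for stressed dyads
    sex_stress_effect: float = -0.12  # added for male * stressed dyads
    cortisol_c_corr: float = 0.3  # target corr(hair cortisol, gain)
    outcome_noise_sd: float = 15.0  # Bayley composite noise SD

    def __post_init__(self) -> None:
        if self.c_sd < 0 or self.outcome_noise_sd < 0:
            raise ValueError("negative variance in effect map")
        if not -1 <= self.cortisol_c_corr <= 1:
            raise ValueError("cortisol_c_corr must be a correlation")


@dataclass(frozen=True)
class CohortSpec:
    n_dyads: int = 118
    stress_fraction: float = 0.5
    male_fraction: float = 0.415
    effects: EffectMap = field(default_factory=EffectMap)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("need at least two dyads")
        if not 0 <= self.stress_fraction <= 1 or not 0 <= self.male_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")


_OUTCOME_COLS = [
    "bayley_cog",
    "bayley_lang",
    "bayley_motor",
    "lang_receptive",
    "lang_expressive",
    "motor_fine",
    "motor_gross",
]


def generate_cohort(
    spec: CohortSpec, with_recordings: bool = True
) -> tuple[pd.DataFrame, list[DyadRecording]]:
    """Generate a cohort table and (optionally) its dyad recordings.

    Group labels are assigned to match the requested fractions exactly
    (``round(n * fraction)`` dyads per group, positions shuffled).  The
    per-dyad coupling gain is ``c_base`` plus the stress and sex-by-stress
    effects plus Gaussian between-dyad noise, floored at zero; each
    recording is then simulated with its own gain and seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_dyads
    eff = spec.effects

    stressed = np.zeros(n, dtype=bool)
    stressed[: int(round(spec.stress_fraction * n))] = True
    rng.shuffle(stressed)
    male = np.zeros(n, dtype=bool)
    male[: int(round(spec.male_fraction * n))] = True
    rng.shuffle(male)

    c = (
        eff.c_base
        + eff.stress_effect * stressed
        + eff.sex_stress_effect * (stressed & male)
        + eff.c_sd * rng.standard_normal(n)
    )
    c = np.maximum(c, 0.0)

    # hair cortisol with the prescribed correlation to the realized gain
    c_sd_obs = np.std(c)
    z_c = (c - np.mean(c)) / c_sd_obs if c_sd_obs > 0 else np.zeros(n)
    r = eff.cortisol_c_corr
    z_cort = r * z_c + np.sqrt(max(1.0 - r**2, 0.0)) * rng.standard_normal(n)
    cortisol = np.maximum(90.0 + 45.0 * z_cort, 5.0)

    pss = np.where(
        stressed,
        np.minimum(19.0 + np.abs(rng.normal(3.0, 3.0, n)), 40.0),
        np.clip(rng.normal(11.0, 4.0, n), 0.0, 18.0),
    ).round(0)
    pdq = np.clip(rng.normal(np.where(stressed, 15.0, 8.0), 4.0), 0, 36).round(0)

    outcomes = {
        col: np.round(100.0 + eff.outcome_noise_sd * rng.standard_normal(n), 1)
        for col in _OUTCOME_COLS
    }

    ids = [f"SIM-{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "dyad_id": ids,
            "group": np.where(stressed, "stressed", "control"),
            "sex": np.where(male, "male", "female"),
            "pss": pss,
            "pdq": pdq,
            "cortisol": np.round(cortisol, 1),
            "coupling_gain_true": np.round(c, 6),
            **outcomes,
        }
    )

    recordings: list[DyadRecording] = []
    if with_recordings:
        child_seeds = np.random.SeedSequence(spec.seed).generate_state(n) % (2**31)
        for i in range(n):
            cfg = replace(spec.sim, coupling_gain=float(c[i]))
            recordings.append(
                generate_dyad(cfg, seed=int(child_seeds[i]), dyad_id=ids[i])
            )
    return table, recordings


def write_cohort(
    table: pd.DataFrame, recordings: list[DyadRecording], out_dir: str | Path
) -> None:
    """Write cohort CSV, per-dyad RR CSVs, quality masks and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "cohort.csv", index=False)
    truth = {}
    for rec in recordings:
        write_rr_csv(rec.maternal_rr, out / f"{rec.dyad_id}_maternal_rr.csv")
        write_rr_csv(rec.fetal_rr, out / f"{rec.dyad_id}_fetal_rr.csv")
        np.savetxt(
            out / f"{rec.dyad_id}_mask.csv",
            rec.quality_mask.astype(int),
            fmt="%d",
            header="good_second",
            comments="",
        )
        truth[rec.dyad_id] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(rec.truth).items()
        }
    pd.Series(truth, dtype=object).to_json(out / "truth.json")
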