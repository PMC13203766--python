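# Methods

`dyadflow` quantifies the direction- and state-dependent information flow
between a maternal and a fetal heart rate recorded simultaneously. This
note documents the model assumptions, the estimators, the synthetic-data
generator that stands in for clinical recordings, and the numerical
choices that an independent re-implementation would need to know.

## Signal model and preprocessing

Input data are per-heart R-R interval series (beat time, interval). The
instantaneous heart rate is HR(t) = 60 / RRI for the interval containing
t, sampled by zero-order hold on an even grid at `fs` (default 20 Hz).
Zero-order hold is the convention consistent with the piece-wise-constant
character of beat-derived heart rate; the conversion routine is isolated
so a different interpolant can be swapped in.

All multiscale quantities are computed from the τ-filtered signal: a
*centered* moving average of `round(τ·fs)` samples. A centered window
avoids introducing a relative phase shift between the maternal and fetal
filtered signals, which matters because the transfer-entropy embedding
pairs samples of both signals at identical times. The same τ serves as
the embedding lag of every estimator, so one parameter selects the time
scale throughout.

Quality control: a per-second boolean mask (supplied with the data, e.g.
from an upstream signal-quality index) invalidates samples; valid runs
shorter than 10 s are discarded because no embedding window fits inside
them. Filtered samples are valid only when their entire window is valid —
filtering never manufactures data inside gaps. Dyads whose fetal HR sits
below 100 bpm (i.e. in the maternal range, indicating a failed fetal
extraction) for more than a configurable fraction of valid samples
(default 0.05; the clinical criterion is qualitative, so this threshold
is explicitly a package default, not a literature value) are excluded.

Timing noise: R peaks localized on a 1 kHz ECG grid carry a per-interval
error of up to Δ(RRI) = 2/f_ECG = 2 ms, which propagates to
ΔHR = HR²·Δ(RRI)/60 ≈ 0.2 bpm at 80 bpm. The estimators treat the
resulting value quantization by seeded uniform jitter (amplitude 10⁻⁶·σ
per embedding dimension), which k-NN estimators require to break ties.

## Epochs

At each scale, samples are labeled by the sign of the forward first
difference of the filtered signal: positive → acceleration, negative →
deceleration, zero (within the threshold μ, default 0) → neither; the
last sample of each valid run is "neither". Maximal same-label runs form
events. Because ties and run endpoints create a third category, the
accel + decel time-point fractions sum to slightly less than one — both
event-count and time-point fractions are reported.

## Information metrics

All entropies are differential, in nats, with the Chebyshev norm and
k = 5 neighbors.

* **Entropy rate** h(τ) = H(x_t, x_{t+L}) − H(x_t), L = round(τ·fs),
  estimated with the Kozachenko–Leonenko estimator:
  H = ψ(n) − ψ(k) + d·ln 2 + (d/n)·Σ ln ε_i.
* **Sample entropy** −ln(A/B): B counts template pairs of length m
  (default 1) within r = 0.2·σ, A the same for m+1; self-matches
  excluded. Template elements are spaced by the scale lag L (the
  multiscale convention — consecutive samples of a smoothed signal are
  nearly identical and would drive SE to zero), and σ is computed on the
  analyzed (possibly conditioned) sample set.
* **Transfer entropy** TE_src→dst(τ) = I(dst_{t+L}; src_t | dst_t),
  estimated with the KSG (algorithm-1) conditional-mutual-information
  scheme. The embedding uses one past lag per signal and a future horizon
  of L; richer embeddings are a configuration knob, and the single-lag
  choice is an explicit modeling assumption.
* **Surrogate bias correction**: corrected TE = raw TE minus the mean of
  `n_surrogates` (default 20) estimates in which the source values are
  circularly shifted by a random offset of at least 10·L *within the
  valid-sample sequence*. Shifting inside the valid sequence (rather than
  on the raw grid) keeps the surrogate ensemble on exactly the embedding
  bases of the raw estimate, so finite-sample bias cancels in the
  subtraction; shifting across quality-mask gaps demonstrably leaves a
  residual bias. The correction subtracts the surrogate mean (a
  percentile-based alternative would give a test, not an estimate).
* **Net TE** = corrected TE_m→f − corrected TE_f→m; positive values mean
  net maternal-to-fetal flow.

Serial correlation: successive embedding vectors of a τ-smoothed signal
are near-duplicates; feeding all of them to a k-NN estimator biases
entropies low because nearest neighbors degenerate to temporal
neighbors. Vectors are therefore taken every `0.25·L` samples
(`stride_fraction`), a compromise between this bias and vector count
that leaves the estimators' closed-form checks (Gaussian, uniform,
Gaussian AR, Gaussian–Granger TE) inside their tolerances. After the
stride, estimates are capped at `max_vectors` (default 4000) randomly
selected vectors to bound k-NN cost, and any estimate with fewer than
`min_vectors` (default 100) is reported missing with a reason rather
than computed.

**Conditioning.** Each metric is evaluated under five paradigms: none,
and accelerations/decelerations of the maternal or fetal filtered HR at
the same scale. A conditioned estimate uses only embedding vectors whose
entire window lies inside one event of the required type, preventing
leakage across regime boundaries. This is deliberately strict: at scales
where events are shorter than the lag the conditioned estimate is
missing, which the pipeline propagates instead of silently relaxing.

**Features.** Metric curves run over a scale grid (default: 1/fs up to
20 s, with six log-spaced points inside the vagal band [0.5, 2.5] s).
Each curve is reduced to its maximum and its mean over the in-band grid
points (the mean equals the area under the curve up to the 2 s band
width; trapezoid integration is available). This yields exactly 50
features per dyad: {ER, SE} × {mHR, fHR} × 5 paradigms × {max, mean}
plus net TE × 5 paradigms × {max, mean}. Transfer entropy, whose
surrogate ensemble dominates compute cost, is evaluated only on in-band
grid points by default (`te_full_grid=True` restores full curves); the
feature reduction uses in-band points only in either case.

## Synthetic dyads

The generator produces the structure the analysis assumes, so every
stage is testable without the (non-public) clinical recordings. Each
heart follows a continuous-time target rate:

    HR(t) = mean + oscillators(t) + AR(1) fast noise + 1/f background

with maternal mean 80 bpm (RR 0.75 s) and fetal mean ≈140 bpm (RR
0.43 s). Oscillators sit in the respiratory (0.25 Hz) and Mayer
(0.10 Hz) bands for the mother and in the fetal breathing-movement
(0.70 Hz) and slow (0.15 Hz) bands for the fetus. The 1/f background is
an AR(1) bank with correlation times 0.5–120 s carrying equal variance
shares; without this low-frequency continuum — which real heart-rate
variability possesses — the signal holds no information at scales beyond
the oscillators and the entropy-rate curve collapses above τ ≈ 5 s
instead of plateauing. The spectral weights (background 4.0 bpm total,
oscillators ≈1–3 bpm) were fixed once so that the unconditioned entropy
rate varies by less than ~25% over τ ∈ [1, 20] s, the qualitative
behavior expected of real HR.

Two asymmetry mechanisms reproduce the slight dominance of acceleration
time over deceleration time seen in real recordings: negatively skewed
AR innovations (sharp drops, slower recoveries) and phase-warped
oscillator waveforms with longer rising flanks; the fetal settings are
stronger than the maternal ones, giving ≈+2% (fetal) and ≈+1.5%
(maternal) accel-minus-decel time fractions at τ = 2.5 s. These
magnitudes are direction-calibrated, not magnitude-calibrated.

**Coupling.** The fetal AR innovations receive an additive drive
c·(1−φ)·m̄(t−δ), where m̄ is the maternal rate moving-averaged over the
lag window δ (default 1.0 s, inside the vagal band) and c (default 0.3)
is the steady-state bpm-per-bpm gain. Coupling is strictly
maternal→fetal. During ground-truth maternal decelerations — the sign
of the derivative of the *smoothed maternal target rate*, independent
of any downstream estimator — the fetal innovation SD is multiplied by
√ρ (default ρ = 0.5), emulating state-contingent quieting of fetal
variability. Note that ρ < 1 by itself constitutes real m→f information
flow; a truly uncoupled dyad needs c = 0 *and* ρ = 1.

Beats are produced by integrate-and-fire on the cumulative phase of
HR/60 and snapped to the ECG grid (1/f_ECG) by stochastic rounding, so
each beat moves by less than one ECG sample and each interval by less
than 2/f_ECG, with zero mean error. A per-second quality mask drops 5%
of seconds at random by default.

**Cohorts.** Group labels match the requested stressed/male fractions
exactly (default 0.5 and 0.415). The coupling gain carries a stress main
effect (+0.06), a male×stress interaction (−0.12) and between-dyad noise
(SD 0.08); hair cortisol is drawn with correlation 0.3 to the realized
gain; perceived-stress scores respect the ≥19 stressed cutoff; the
neurodevelopmental outcomes are noise (SD 15 around 100) unless given an
effect. These effect sizes are free choices of the simulator — the study
this emulates reports model coefficients on entropy features, not
generative gains — and their signs follow the reported directions.

## Cohort statistics

* **Net-TE positivity**: per feature, the probability of a
  zero-or-negative cohort net TE under a Gaussian fitted to the cohort
  distribution, evaluated for the sample mean (Φ(−mean·√n/sd)), plus a
  one-sided one-sample t-test; the two agree closely for n ≥ 50. Both
  are reported per stratum (cohort, stress groups, sexes) after removing
  extreme outliers (leave-one-out |z| > 10; leave-one-out because a
  single gross outlier otherwise inflates the scale enough to mask
  itself).
* **Mixed models**: REML linear mixed models with a random intercept per
  dyad (statsmodels `MixedLM`), over long-format tables — event-type
  fractions (4 rows/dyad), ER/SE/TE features (10–20 rows/dyad). Presets
  fix the factor coding: reference levels are the fetal signal,
  fetal-acceleration conditioning, the max summary, female sex and the
  control group. Covariate adjustment (e.g. gestational age, maternal
  age, BMI) is a sensitivity option. Degenerate designs (empty factor
  cells in small cohorts) are flagged as non-converged, not raised.
* **Coupling strength**: |β_conditioned| / β_no-conditioning from the
  entropy-rate model, undefined (flagged) for a non-positive baseline.
* **Correlation battery**: for each feature–outcome pair
  (pairwise-complete, n ≥ 5), Shapiro–Wilk (α = 0.05) on both variables
  selects Pearson (both normal) or Spearman; Benjamini–Hochberg q-values
  are computed over all tests of one stratum's battery, and strata
  (stress, sex) re-run as separate batteries. Two-tailed p at α = 0.05;
  missing features are dropped pairwise, never imputed.

## What the synthetic tests do and do not show

Passing the recovery suite shows the estimators detect the directions
and orderings they should under the generator's assumptions: linear
lagged coupling, variance-gated state dependence, AR/oscillator
spectra, stationarity over the recording. Real recordings add
nonstationary behavioral states, movement artifacts surviving the
quality mask, nonlinear autonomic responses and gestational-age trends
— none of which the generator emulates. Cohort-level clinical numbers
(specific p-values, β magnitudes, correlation coefficients) are
therefore not reproducible here; the test suite checks signs, orderings,
calibration under nulls, and estimator accuracy against closed forms.

## Problem sizes and numerical defaults

The test and acceptance runs use scaled-down study conditions chosen as
the package's own defaults for desk-scale verification: 5–40-minute
recordings, cohorts of 20–50 dyads, 8–20 surrogates, 1500–5000 embedding
vectors per estimate, and three to six in-band scale points. Estimator
tolerances: k-NN entropy vs closed forms ±0.05 nats at n = 10⁴; KSG TE
vs the Gaussian–Granger oracle within 10% at n = 2·10⁴; sample entropy
agrees exactly with exhaustive counting. Seeds are explicit everywhere;
identical configuration and seed reproduce outputs bit-for-bit.

## Known limitations

* Single-lag embeddings understate history effects for strongly
  autocorrelated destinations; the lag structure is configurable but
  untested beyond one lag.
* Conditioned estimates at scales comparable to epoch durations are
  frequently missing by design; analyses should treat missingness as
  informative of epoch geometry, not failure.
* The Gaussian positivity test and the t-test are near-duplicates at
  cohort sizes here; both are kept for comparability with the two
  conventions in the field.
* The correlation battery treats each stratum's battery as its own BH
  family; with heavily correlated features the effective number of tests
  is far below the nominal count, making the correction conservative.
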