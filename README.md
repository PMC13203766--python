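# dyadflow

Multiscale, event-conditioned information flow between maternal and
fetal heart rates.

During the third trimester the two hearts of a mother–fetus dyad are not
independent: the maternal heart rate (mHR) carries information about the
fetal heart rate's (fHR) future, and fetal variability is quieted during
maternal decelerations. `dyadflow` quantifies both phenomena from
ordinary R-R interval series, for researchers in fetal physiology,
prenatal-stress programming and physiological time-series analysis who
need a tested, reproducible implementation — including a synthetic
coupled-dyad generator, since clinical recordings of this kind are
rarely shareable.

## The model

Every quantity is computed from the τ-filtered heart rate (centered
moving average, window τ; default grid from 1/fs up to 20 s) sampled at
`fs` = 20 Hz, with τ also serving as the embedding lag:

- **Entropy rate** h(τ) = H(x_t, x_{t+τ}) − H(x_t) — the rate of new
  information generation, via the Kozachenko–Leonenko k-NN estimator
  (k = 5, Chebyshev norm, nats).
- **Sample entropy** −ln(A/B) with m = 1, r = 0.2σ — signal regularity.
- **Transfer entropy** TE_m→f(τ) = I(fHR_{t+τ}; mHR_t | fHR_t) via the
  Kraskov–Stögbauer–Grassberger conditional-MI scheme, bias-corrected by
  circular time-shift surrogates of the source, reported bidirectionally
  and as **net TE** = TE_m→f − TE_f→m (positive = net maternal-to-fetal
  flow).

Each metric is evaluated under five conditioning paradigms — no
conditioning, or restricted to acceleration/deceleration epochs of the
maternal or fetal signal (epochs = sign of the filtered-HR derivative at
the same τ) — and each curve is reduced to its maximum and mean over the
vagal band τ ∈ [0.5, 2.5] s, yielding 50 features per dyad. Cohort-level
inference covers net-TE positivity tests, REML mixed models with random
intercepts per dyad (from which the coupling-strength ratio
|β_conditioned| / β_baseline is derived), and a normality-driven,
BH-FDR-controlled feature–outcome correlation battery.

See `docs/methods.md` for assumptions, estimator details and the
synthetic-data model.

## Worked example

Simulate one 20-minute dyad with the default one-way maternal→fetal
coupling (gain 0.3, lag 1 s) and deceleration-gated fetal variance
(ρ = 0.5), then fit the per-dyad model:

```python
from dyadflow import (SimConfig, generate_dyad, DyadEntropyModel,
                      EntropyParams, ScaleGrid)

rec = generate_dyad(SimConfig(duration=1200.0), seed=7, dyad_id="DEMO-007")
model = DyadEntropyModel.from_recording(
    rec, grid=ScaleGrid(taus=(0.5, 1.0, 1.6, 2.5, 5.0)),
    params=EntropyParams(n_surrogates=10, max_vectors=3000),
)
res = model.fit()
print(res.summary())
```

```
Dyad DEMO-007
  valid maternal samples: 20957
  valid fetal samples:    20964
  excluded (fHR in maternal range): False (fraction 0.000)
  features computed: 50/50 (0 missing)
  net TE max, no conditioning: +0.0124 nats
  ER fHR max, no conditioning: +2.8144 nats
```

The positive net TE maximum (+0.012 nats in the vagal band) recovers the
planted maternal→fetal direction of information flow; the one-way flows
it is the difference of are an order of magnitude larger. The fetal
entropy rate drops from 2.81 nats (unconditioned) to 2.34 nats during
maternal decelerations (`res.features.features["er_fhr_mhr_decel_max"]`)
— the deceleration-gated quieting of fetal variability, exactly the
state-dependent coupling signature the conditioning framework is built
to expose.

Cohort runs go through `CohortCouplingModel(features, cohort_table).fit()`
or the CLI:

```bash
dyadflow all --n-dyads 10 --duration 600 --seed 1 --out run1
dyadflow sensitivity --out run1 --rates 4,20   # fs robustness sweep
```

which writes `features.csv` (10 rows × 50 feature columns), mixed-model
term tables, the net-TE positivity table and the correlation battery.

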