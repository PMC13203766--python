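"""Cohort-level statistics for the entropy feature tables.

Three stages mirror the analysis battery the features feed into:

* positivity tests of the cohort net transfer entropy (a one-sided
  probability under a Gaussian fitted to the cohort distribution, and a
  one-sided one-sample t-test);
* repeated-measures mixed linear models (REML, random intercept per
  dyad) over long-format feature tables, from which a coupling-strength
  ratio |beta_conditioned| / beta_baseline is derived;
* an exploratory correlation battery between features and outcomes with
  normality-driven method choice (Shapiro–Wilk at alpha = 0.05 on both
  variables selects Pearson, otherwise Spearman), Benjamini–Hochberg FDR
  over the whole battery, and optional stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NetTETest",
    "test_net_te_positive",
    "filter_outliers",
    "OutlierReport",
    "MLMSpec",
    "MLMResult",
    "fit_mlm",
    "MLM_PRESETS",
    "build_fraction_long_table",
    "build_entropy_long_table",
    "CouplingStrength",
    "coupling_strength",
    "run_correlation_battery",
    "expected_false_positives",
]


# ---------------------------------------------------------------------------
# net-TE positivity


@dataclass(frozen=True)
class NetTETest:
    n: int
    mean: float
    sd: float
    gaussian_p: float
    t_p: float
    degenerate: bool = False


def test_net_te_positive(values: np.ndarray) -> NetTETest:
    """Probability of a zero-or-negative cohort net TE under a fitted
    Gaussian, plus a one-sided one-sample t-test of mean > 0.

    ``gaussian_p`` is P(mean <= 0) for the sample mean of a Gaussian with
    the cohort's fitted mean and SD, i.e. Phi(-mean / (sd / sqrt(n)));
    it converges to the t-test p-value as n grows.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("need at least three values")
    mean, sd = float(np.mean(v)), float(np.std(v, ddof=1))
    if sd == 0:
        p = 0.5 if mean == 0 else (0.0 if mean > 0 else 1.0)
        return NetTETest(len(v), mean, sd, p, p, degenerate=True)
    gaussian_p = float(sps.norm.cdf(0.0, loc=mean, scale=sd / np.sqrt(len(v))))
    t_p = float(sps.ttest_1samp(v, 0.0, alternative="greater").pvalue)
    return NetTETest(len(v), mean, sd, gaussian_p, t_p)


@dataclass(frozen=True)
class OutlierReport:
    kept: np.ndarray  # indices into the input
    removed: list[tuple[int, float]]  # (index, z at removal)
    zero_variance: bool = False


def filter_outliers(values: np.ndarray, z_max: float = 10.0) -> OutlierReport:
    """Iteratively drop points with |z| > z_max.

    Each point's z-score is computed from the mean and SD of the
    *remaining* points (leave-one-out), so a single gross outlier cannot
    mask itself by inflating the scale estimate.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least three values")
    kept = np.arange(len(v))
    removed: list[tuple[int, float]] = []
    while len(kept) > 3:
        x = v[kept]
        n = len(x)
        s, ss = x.sum(), (x**2).sum()
        loo_mean = (s - x) / (n - 1)
        loo_var = np.maximum((ss - x**2 - (n - 1) * loo_mean**2) / (n - 2), 0.0)
        if np.all(loo_var == 0):
            return OutlierReport(kept, removed, zero_variance=True)
        z = (x - loo_mean) / np.sqrt(np.maximum(loo_var, 1e-300))
        worst = int(np.argmax(np.abs(z)))
        if np.abs(z[worst]) <= z_max:
            break
        removed.append((int(kept[worst]), float(z[worst])))
        kept = np.delete(kept, worst)
    if np.std(v[kept], ddof=1) == 0:
        return OutlierReport(kept, removed, zero_variance=True)
    return OutlierReport(kept, removed)


# ---------------------------------------------------------------------------
# mixed linear models


@dataclass(frozen=True)
class MLMSpec:
    """A mixed-model specification over a long-format feature table.

    ``formula`` is a statsmodels/patsy fixed-effects formula; the model
    adds a random intercept per ``group_col``.  ``covariates`` are extra
    additive terms for sensitivity analyses (e.g. gestational age at
    birth, maternal age, BMI).
    """

    formula: str
    group_col: str = "dyad_id"
    covariates: tuple[str, ...] = ()

    def full_formula(self) -> str:
        if not self.covariates:
            return self.formula
        return self.formula + " + " + " + ".join(self.covariates)


@dataclass(frozen=True)
class MLMResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    n_obs: int
    n_groups: int
    model: object = None

    def term_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "se": self.bse, "p": self.pvalues}
        )


# Named presets mirroring the three repeated-measures analyses: event-type
# fractions, entropy rate under conditioning, and transfer entropy.
# Reference levels are fixed by the Treatment coding below: fetal signal,
# fetal-acceleration conditioning, max summary, female sex, control group.
MLM_PRESETS: dict[str, MLMSpec] = {
    "fractions": MLMSpec(
        "value ~ C(hr_source, Treatment('fhr')) * C(event_type, Treatment('accel'))"
        " + C(sex, Treatment('female')) * C(group, Treatment('control'))"
    ),
    "entropy_rate": MLMSpec(
        "value ~ C(paradigm, Treatment('fhr_accel')) + C(hr_source, Treatment('fhr'))"
        " + C(summary, Treatment('max'))"
        " + C(sex, Treatment('female')) * C(group, Treatment('control'))"
    ),
    "sample_entropy": MLMSpec(
        "value ~ C(paradigm, Treatment('fhr_accel')) * C(hr_source, Treatment('fhr'))"
        " + C(summary, Treatment('max'))"
        " + C(sex, Treatment('female')) * C(group, Treatment('control'))"
    ),
    "transfer_entropy": MLMSpec(
        "value ~ C(paradigm, Treatment('fhr_accel')) * C(summary, Treatment('max'))"
        " + C(sex, Treatment('female')) * C(group, Treatment('control'))"
    ),
}


def fit_mlm(long_table: pd.DataFrame, spec: MLMSpec) -> MLMResult:
    """Fit a REML mixed model with a random intercept per subject.

    Estimation is delegated to statsmodels ``MixedLM``; non-convergence is
    flagged on the result rather than raised, and the partial fit is
    returned.
    """
    df = long_table.dropna(subset=["value"]).copy()
    if df[spec.group_col].nunique() < 2:
        raise ValueError("grouping factor needs at least two subjects")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(spec.full_formula(), df, groups=df[spec.group_col])
            fit = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError):
        # singular or degenerate design (e.g. an empty factor cell)
        empty = pd.Series(dtype=float)
        return MLMResult(
            params=empty, bse=empty, pvalues=empty, converged=False,
            n_obs=len(df), n_groups=df[spec.group_col].nunique(),
        )
    fe = fit.fe_params.index
    return MLMResult(
        params=fit.params[fe],
        bse=fit.bse[fe],
        pvalues=fit.pvalues[fe],
        converged=bool(fit.converged),
        n_obs=len(df),
        n_groups=df[spec.group_col].nunique(),
        model=fit,
    )


def build_fraction_long_table(
    epoch_table: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Long table of time-point accel/decel fractions: 4 rows per dyad
    (2 HR sources x 2 event types), joined with the cohort factors.

    ``epoch_table`` needs columns dyad_id, hr_source, accel_fraction_time,
    decel_fraction_time.
    """
    rows = []
    for _, r in epoch_table.iterrows():
        for event_type, col in (
            ("accel", "accel_fraction_time"),
            ("decel", "decel_fraction_time"),
        ):
            rows.append(
                {
                    "dyad_id": r["dyad_id"],
                    "hr_source": r["hr_source"],
                    "event_type": event_type,
                    "value": r[col],
                }
            )
    return pd.merge(pd.DataFrame(rows), cohort[["dyad_id", "group", "sex"]], on="dyad_id")


def build_entropy_long_table(
    feature_table: pd.DataFrame, cohort: pd.DataFrame, metric: str
) -> pd.DataFrame:
    """Melt a wide feature table into the repeated-measures layout.

    One row per dyad x signal x paradigm x summary for ``metric`` in
    {'er', 'se', 'net_te'}; missing features are dropped.
    """
    prefix = metric + "_"
    cols = [c for c in feature_table.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no '{metric}' feature columns found")
    long = feature_table.melt(
        id_vars="dyad_id", value_vars=cols, var_name="feature", value_name="value"
    ).dropna(subset=["value"])
    parts = long["feature"].str.slice(len(prefix)).str.rsplit("_", n=1, expand=True)
    rest, long["summary"] = parts[0], parts[1]
    signal = rest.str.split("_", n=1, expand=True)
    long["hr_source"], long["paradigm"] = signal[0], signal[1]
    long["paradigm_is_none"] = long["paradigm"] == "none"
    return pd.merge(long, cohort[["dyad_id", "group", "sex"]], on="dyad_id")


@dataclass(frozen=True)
class CouplingStrength:
    beta_conditioned: float
    beta_baseline: float
    ratio: float
    defined: bool


def coupling_strength(beta_conditioned: float, beta_baseline: float) -> CouplingStrength:
    """Coupling strength |beta_conditioned| / beta_baseline.

    The conditioned coefficient (e.g. the entropy change during maternal
    decelerations) is measured against the no-conditioning baseline
    coefficient; the ratio expresses how much of the available dynamic
    range the conditioned state captures.  Undefined for a non-positive
    baseline.
    """
    if beta_baseline <= 0:
        return CouplingStrength(beta_conditioned, beta_baseline, np.nan, False)
    return CouplingStrength(
        beta_conditioned, beta_baseline, abs(beta_conditioned) / beta_baseline, True
    )


# ---------------------------------------------------------------------------
# correlation battery


def expected_false_positives(n_tests: int, alpha: float) -> float:
    """Expected count of spurious discoveries: n_tests * alpha."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return n_tests * alpha


def _one_correlation(x: np.ndarray, y: np.ndarray, alpha: float):
    """Method choice per pair: Pearson iff both pass Shapiro–Wilk."""
    normal = (
        sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
        if len(x) >= 3
        else False
    )
    if normal:
        r, p = sps.pearsonr(x, y)
        return "pearson", float(r), float(p)
    res = sps.spearmanr(x, y)
    return "spearman", float(res.statistic), float(res.pvalue)


def run_correlation_battery(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    feature_cols: list[str] | None = None,
    outcome_cols: list[str] | None = None,
    strata: dict[str, pd.Series] | None = None,
    alpha: float = 0.05,
    min_n: int = 5,
) -> pd.DataFrame:
    """Feature-outcome correlation battery with BH-FDR per stratum run.

    For every feature-outcome pair (pairwise-complete observations) the
    method is chosen by normality of both variables; BH q-values are
    computed over all tests of one stratum's battery, the paper-style
    convention of treating each (sub)cohort run as its own family.

    Parameters
    ----------
    features, outcomes : DataFrame
        Joined on ``dyad_id``.
    strata : dict, optional
        Maps stratum name to a boolean Series (indexed like the join) or
        is omitted for the full-cohort battery only.
    """
    df = pd.merge(features, outcomes, on="dyad_id")
    feature_cols = feature_cols or [
        c for c in features.columns if c != "dyad_id" and pd.api.types.is_numeric_dtype(features[c])
    ]
    outcome_cols = outcome_cols or [
        c for c in outcomes.columns if c != "dyad_id" and pd.api.types.is_numeric_dtype(outcomes[c])
    ]
    all_strata = {"all": pd.Series(True, index=df.index)}
    if strata:
        all_strata.update(strata)
    records = []
    for stratum, sel in all_strata.items():
        sub = df[np.asarray(sel, dtype=bool)]
        batch = []
        for f in feature_cols:
            for o in outcome_cols:
                pair = sub[[f, o]].dropna()
                if len(pair) < min_n:
                    continue
                x, y = pair[f].to_numpy(), pair[o].to_numpy()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    method, r, p = _one_correlation(x, y, alpha)
                batch.append(
                    {
                        "feature": f,
                        "outcome": o,
                        "stratum": stratum,
                        "method": method,
                        "r": r,
                        "p": p,
                        "n": len(pair),
                    }
                )
        if batch:
            ps = np.array([b["p"] for b in batch])
            qs = multipletests(ps, method="fdr_bh")[1]
            for b, q in zip(batch, qs):
                b["q"] = float(q)
            records.extend(batch)
    return pd.DataFrame(
        records, columns=["feature", "outcome", "stratum", "method", "r", "p", "q", "n"]
    )
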