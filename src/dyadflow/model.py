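"""Model/Results interface over the per-dyad and cohort pipelines.

Two fitting objects wrap the functional modules in the familiar
model-object idiom: build the model from data, call :meth:`fit`, read the
results.

* :class:`DyadEntropyModel` — one dyad's RR data in, a
  :class:`DyadEntropyResults` with the 50-feature vector and the metric
  curves out.
* :class:`CohortCouplingModel` — a cohort's feature and covariate tables
  in, a :class:`CohortCouplingResults` with net-TE positivity tests,
  mixed-model term tables, coupling-strength ratios and the correlation
  battery out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cohort_stats
from .epochs import epoch_stats, label_epochs
from .infotheory import (
    EntropyParams,
    FeatureResult,
    PreparedDyad,
    ScaleGrid,
    compute_features,
)
from .preprocess import dyad_exclusion, moving_average

__all__ = [
    "DyadEntropyModel",
    "DyadEntropyResults",
    "CohortCouplingModel",
    "CohortCouplingResults",
]


class DyadEntropyModel:
    """Multiscale entropy/coupling analysis of one maternal–fetal dyad.

    Parameters
    ----------
    prep : PreparedDyad
        Maternal and fetal HR on a shared grid (see
        :meth:`PreparedDyad.from_recording`).
    grid : ScaleGrid, optional
    params : EntropyParams, optional
    epoch_tau : float
        Scale at which the accel/decel event statistics are reported
        (2.5 s by default, the upper edge of the vagal band).
    """

    def __init__(
        self,
        prep: PreparedDyad,
        grid: ScaleGrid | None = None,
        params: EntropyParams | None = None,
        epoch_tau: float = 2.5,
    ) -> None:
        self.prep = prep
        self.grid = grid or ScaleGrid.default(prep.mhr.fs)
        self.params = params or EntropyParams()
        self.epoch_tau = epoch_tau

    @classmethod
    def from_recording(cls, recording, fs: float = 20.0, **kwargs) -> "DyadEntropyModel":
        return cls(PreparedDyad.from_recording(recording, fs=fs), **kwargs)

    def fit(self, te_full_grid: bool = False) -> "DyadEntropyResults":
        exclusion = dyad_exclusion(self.prep.fhr, self.prep.mhr)
        feats = compute_features(
            self.prep, self.grid, self.params, te_full_grid=te_full_grid
        )
        epoch_rows = []
        for source, series in (("mhr", self.prep.mhr), ("fhr", self.prep.fhr)):
            mask = label_epochs(moving_average(series, self.epoch_tau))
            st = epoch_stats(mask)
            epoch_rows.append(
                {
                    "dyad_id": self.prep.dyad_id,
                    "hr_source": source,
                    "tau_s": self.epoch_tau,
                    "n_accel": st.n_accel,
                    "n_decel": st.n_decel,
                    "accel_fraction_time": st.accel_fraction_time,
                    "decel_fraction_time": st.decel_fraction_time,
                    "accel_fraction_events": st.accel_fraction_events,
                    "decel_fraction_events": st.decel_fraction_events,
                    "decel_accel_ratio": st.decel_accel_ratio,
                }
            )
        return DyadEntropyResults(
            model=self,
            features=feats,
            epoch_table=pd.DataFrame(epoch_rows),
            exclusion=exclusion,
        )


@dataclass
class DyadEntropyResults:
    model: DyadEntropyModel
    features: FeatureResult
    epoch_table: pd.DataFrame
    exclusion: object

    @property
    def feature_row(self) -> pd.DataFrame:
        return self.features.to_frame()

    @property
    def curves(self) -> pd.DataFrame:
        return self.features.curves

    def summary(self) -> str:
        f = self.features.features
        lines = [
            f"Dyad {self.features.dyad_id}",
            f"  valid maternal samples: {self.model.prep.mhr.n_valid}",
            f"  valid fetal samples:    {self.model.prep.fhr.n_valid}",
            f"  excluded (fHR in maternal range): {self.exclusion.excluded}"
            f" (fraction {self.exclusion.low_fhr_fraction:.3f})",
            f"  features computed: {sum(np.isfinite(list(f.values())))}/50"
            f" ({len(self.features.missing)} missing)",
            f"  net TE max, no conditioning: {f['net_te_pair_none_max']:+.4f} nats",
            f"  ER fHR max, no conditioning: {f['er_fhr_none_max']:+.4f} nats",
        ]
        return "\n".join(lines)


class CohortCouplingModel:
    """Cohort-level battery over a wide feature table and cohort covariates.

    Parameters
    ----------
    feature_table : DataFrame
        One row per dyad, the 50 feature columns plus ``dyad_id``.
    cohort : DataFrame
        Per-dyad factors and outcomes (``group``, ``sex``, stress scores,
        cortisol, neurodevelopmental scores).
    epoch_table : DataFrame, optional
        Per dyad x hr_source event fractions for the fraction mixed model.
    """

    NET_TE_FEATURES = [
        f"net_te_pair_{p}_{s}"
        for p in ("none", "mhr_accel", "mhr_decel", "fhr_accel", "fhr_decel")
        for s in ("max", "auc")
    ]

    def __init__(
        self,
        feature_table: pd.DataFrame,
        cohort: pd.DataFrame,
        epoch_table: pd.DataFrame | None = None,
        outcome_cols: tuple[str, ...] = (
            "cortisol",
            "pss",
            "pdq",
            "bayley_cog",
            "bayley_lang",
            "bayley_motor",
        ),
        z_max: float = 10.0,
    ) -> None:
        self.feature_table = feature_table
        self.cohort = cohort
        self.epoch_table = epoch_table
        self.outcome_cols = [c for c in outcome_cols if c in cohort.columns]
        self.z_max = z_max

    def fit(
        self,
        battery_features: list[str] | None = None,
        stratify: bool = True,
        covariates: tuple[str, ...] = (),
    ) -> "CohortCouplingResults":
        merged = pd.merge(
            self.feature_table, self.cohort, on="dyad_id", how="inner"
        )

        # net-TE positivity per paradigm/summary, cohort and strata,
        # after extreme-outlier removal
        net_tests: dict[str, dict[str, cohort_stats.NetTETest]] = {}
        strata = {"all": pd.Series(True, index=merged.index)}
        if stratify:
            strata.update(
                {
                    "stressed": merged["group"] == "stressed",
                    "control": merged["group"] == "control",
                    "male": merged["sex"] == "male",
                    "female": merged["sex"] == "female",
                }
            )
        outlier_reports = {}
        for feat in self.NET_TE_FEATURES:
            if feat not in merged.columns:
                continue
            vals = merged[feat].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            rep = cohort_stats.filter_outliers(vals[finite], self.z_max)
            outlier_reports[feat] = rep
            keep_idx = np.flatnonzero(finite)[rep.kept]
            keep = np.zeros(len(merged), dtype=bool)
            keep[keep_idx] = True
            net_tests[feat] = {}
            for name, sel in strata.items():
                sub = vals[keep & np.asarray(sel, dtype=bool)]
                if len(sub) >= 3:
                    net_tests[feat][name] = cohort_stats.test_net_te_positive(sub)

        # mixed models
        mlm_results: dict[str, cohort_stats.MLMResult] = {}
        if self.epoch_table is not None:
            long = cohort_stats.build_fraction_long_table(self.epoch_table, self.cohort)
            spec = cohort_stats.MLM_PRESETS["fractions"]
            if covariates:
                spec = cohort_stats.MLMSpec(spec.formula, spec.group_col, covariates)
            mlm_results["fractions"] = cohort_stats.fit_mlm(long, spec)
        for metric, preset in (
            ("er", "entropy_rate"),
            ("se", "sample_entropy"),
            ("net_te", "transfer_entropy"),
        ):
            try:
                long = cohort_stats.build_entropy_long_table(
                    self.feature_table, self.cohort, metric
                )
            except ValueError:
                continue
            spec = cohort_stats.MLM_PRESETS[preset]
            if covariates:
                spec = cohort_stats.MLMSpec(spec.formula, spec.group_col, covariates)
            mlm_results[preset] = cohort_stats.fit_mlm(long, spec)

        coupling = self._coupling_strengths(mlm_results.get("entropy_rate"))

        battery = cohort_stats.run_correlation_battery(
            self.feature_table,
            merged[["dyad_id"] + self.outcome_cols],
            feature_cols=battery_features,
            strata={k: v for k, v in strata.items() if k != "all"} if stratify else None,
        )
        return CohortCouplingResults(
            model=self,
            net_te_tests=net_tests,
            outlier_reports=outlier_reports,
            mlm_results=mlm_results,
            coupling=coupling,
            battery=battery,
        )

    @staticmethod
    def _coupling_strengths(er_result) -> dict[str, cohort_stats.CouplingStrength]:
        """Coupling-strength ratios from the entropy-rate model terms.

        The baseline is the no-conditioning coefficient (relative to the
        fetal-acceleration reference); each conditioned coefficient is
        expressed as a fraction of it.
        """
        if er_result is None:
            return {}
        prefix = "C(paradigm, Treatment('fhr_accel'))[T."
        terms = {
            name[len(prefix):-1]: float(beta)
            for name, beta in er_result.params.items()
            if name.startswith(prefix)
        }
        base = terms.get("none")
        if base is None:
            return {}
        return {
            paradigm: cohort_stats.coupling_strength(beta, base)
            for paradigm, beta in terms.items()
            if paradigm != "none"
        }


@dataclass
class CohortCouplingResults:
    model: CohortCouplingModel
    net_te_tests: dict
    outlier_reports: dict
    mlm_results: dict
    coupling: dict
    battery: pd.DataFrame

    def net_te_table(self) -> pd.DataFrame:
        """Gaussian positivity p-values, rows = strata, columns = features."""
        rows = {}
        for feat, per_stratum in self.net_te_tests.items():
            for stratum, test in per_stratum.items():
                rows.setdefault(stratum, {})[feat] = test.gaussian_p
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            f"Cohort coupling analysis: {len(self.model.feature_table)} dyads",
            "",
            "Net-TE positivity (Gaussian one-sided p, full cohort):",
        ]
        for feat, per_stratum in self.net_te_tests.items():
            if "all" in per_stratum:
                t = per_stratum["all"]
                lines.append(
                    f"  {feat:28s} mean={t.mean:+.4f} p={t.gaussian_p:.3f}"
                )
        if self.coupling:
            lines.append("")
            lines.append("Coupling strength vs no-conditioning baseline (ER model):")
            for paradigm, cs in self.coupling.items():
                ratio = f"{cs.ratio:.3f}" if cs.defined else "undefined"
                lines.append(
                    f"  {paradigm:12s} beta={cs.beta_conditioned:+.4f} ratio={ratio}"
                )
        if len(self.battery):
            n_nom = int((self.battery.p < 0.05).sum())
            n_fdr = int((self.battery.q < 0.05).sum())
            lines.append("")
            lines.append(
                f"Correlation battery: {len(self.battery)} tests, "
                f"{n_nom} with p<0.05, {n_fdr} surviving FDR"
            )
        return "\n".join(lines)
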