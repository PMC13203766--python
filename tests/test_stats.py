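"""Cohort statistics: positivity tests, mixed models, correlation battery."""

import numpy as np
import pandas as pd
import pytest

from dyadflow import (
    MLM_PRESETS,
    coupling_strength,
    expected_false_positives,
    filter_outliers,
    fit_mlm,
    run_correlation_battery,
)
from dyadflow.stats import test_net_te_positive as net_te_positivity
from dyadflow.infotheory import PARADIGMS
from dyadflow.stats import build_entropy_long_table, build_fraction_long_table


class TestNetTEPositivity:
    def test_degenerate_all_positive(self):
        t = net_te_positivity(np.ones(10))
        assert t.degenerate and t.gaussian_p == 0.0

    def test_zero_mean_gives_half(self):
        t = net_te_positivity(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert t.gaussian_p == pytest.approx(0.5)

    def test_gaussian_and_t_agree_for_large_n(self, rng):
        v = rng.normal(0.3, 1.0, size=200)
        t = net_te_positivity(v)
        assert abs(t.gaussian_p - t.t_p) < 0.02

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            net_te_positivity(np.array([1.0, 2.0]))


class TestOutlierFilter:
    def test_clean_sample_untouched(self, rng):
        rep = filter_outliers(rng.standard_normal(118))
        assert len(rep.removed) == 0 and len(rep.kept) == 118

    def test_planted_extreme_point_removed(self, rng):
        v = rng.standard_normal(118)
        v[17] = 24.0
        rep = filter_outliers(v)
        assert [i for i, _ in rep.removed] == [17]

    def test_all_equal_flagged(self):
        rep = filter_outliers(np.full(20, 3.0))
        assert rep.zero_variance and len(rep.kept) == 20


def simulate_fraction_table(rng, n_subj=118, event_beta=-0.061, interaction=0.028):
    rows = []
    for i in range(n_subj):
        u = rng.normal(0, 0.01)
        sex = "male" if i % 3 == 0 else "female"
        grp = "stressed" if i % 2 else "control"
        for src in ("mhr", "fhr"):
            for ev in ("accel", "decel"):
                val = (
                    0.5
                    + u
                    + (event_beta if ev == "decel" else 0.0)
                    + (interaction if (src == "mhr" and ev == "decel") else 0.0)
                    + rng.normal(0, 0.015)
                )
                rows.append(
                    dict(dyad_id=i, hr_source=src, event_type=ev, sex=sex, group=grp, value=val)
                )
    return pd.DataFrame(rows)


def simulate_te_long_table(rng, n_subj=118, stress=0.023, sex_stress=-0.042):
    rows = []
    for i in range(n_subj):
        u = rng.normal(0, 0.04)
        sex = "male" if i % 2 else "female"
        grp = "stressed" if i % 4 < 2 else "control"
        for par in PARADIGMS:
            for summ in ("max", "auc"):
                val = (
                    0.1
                    + u
                    + stress * (grp == "stressed")
                    + sex_stress * ((grp == "stressed") and (sex == "male"))
                    - 0.077 * (summ == "auc")
                    + rng.normal(0, 0.05)
                )
                rows.append(
                    dict(dyad_id=i, paradigm=par, summary=summ, sex=sex, group=grp, value=val)
                )
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_event_type_effect_recovered_at_cohort_scale(self, rng):
        """A planted deceleration deficit of -0.061 (472 obs, 118 subjects)
        is recovered within 2 SE with p < 0.001."""
        df = simulate_fraction_table(rng)
        res = fit_mlm(df, MLM_PRESETS["fractions"])
        term = "C(event_type, Treatment('accel'))[T.decel]"
        assert res.converged
        assert abs(res.params[term] - (-0.061)) < 2 * res.bse[term] + 0.005
        assert res.pvalues[term] < 1e-3

    def test_null_model_produces_no_spurious_effects(self, rng):
        df = simulate_fraction_table(rng, event_beta=0.0, interaction=0.0)
        res = fit_mlm(df, MLM_PRESETS["fractions"])
        term = "C(event_type, Treatment('accel'))[T.decel]"
        assert abs(res.params[term]) < 3 * res.bse[term]

    def test_sex_stress_interaction_sign_recovery(self):
        """The planted sex-by-stress deficit on transfer entropy is recovered
        with the correct sign in >= 90% of simulated cohorts."""
        term = "C(sex, Treatment('female'))[T.male]:C(group, Treatment('control'))[T.stressed]"
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            df = simulate_te_long_table(np.random.default_rng(seed))
            res = fit_mlm(df, MLM_PRESETS["transfer_entropy"])
            hits += res.converged and res.params[term] < 0
        assert hits >= 9

    def test_covariate_adjustment_runs(self, rng):
        df = simulate_fraction_table(rng)
        df["maternal_age"] = rng.normal(33, 4, size=len(df))
        from dyadflow.stats import MLMSpec

        spec = MLM_PRESETS["fractions"]
        res = fit_mlm(df, MLMSpec(spec.formula, covariates=("maternal_age",)))
        assert res.converged
        assert any("maternal_age" in ix for ix in res.params.index)


class TestCouplingStrength:
    @pytest.mark.parametrize(
        "cond,base,expected",
        [(-0.123, 0.206, 0.597), (-0.082, 0.206, 0.398), (0.0, 0.5, 0.0)],
    )
    def test_ratio(self, cond, base, expected):
        cs = coupling_strength(cond, base)
        assert cs.defined and cs.ratio == pytest.approx(expected, abs=0.0005)

    def test_nonpositive_baseline_undefined(self):
        assert not coupling_strength(-0.1, 0.0).defined

    def test_scale_invariance(self):
        a = coupling_strength(-0.123, 0.206).ratio
        b = coupling_strength(-1.23, 2.06).ratio
        assert a == pytest.approx(b)


class TestCorrelationBattery:
    def test_expected_false_positive_arithmetic(self):
        assert expected_false_positives(144, 0.05) == pytest.approx(7.2)
        assert expected_false_positives(0, 0.05) == 0.0
        assert expected_false_positives(30, 0.05) == pytest.approx(1.5)

    def test_monotone_nonlinear_pair_uses_spearman(self, rng):
        n = 60
        x = rng.uniform(size=n)
        feats = pd.DataFrame({"dyad_id": range(n), "f_mono": x, "f_noise": rng.standard_normal(n)})
        outs = pd.DataFrame({"dyad_id": range(n), "o": np.exp(5 * x)})
        bat = run_correlation_battery(feats, outs)
        row = bat[(bat.feature == "f_mono")].iloc[0]
        assert row.method == "spearman"
        assert row.r == pytest.approx(1.0)
        assert row.q <= bat.q.min() + 1e-12

    def test_bh_q_dominates_p(self, rng):
        n = 50
        feats = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"f{i}" for i in range(6)])
        feats.insert(0, "dyad_id", range(n))
        outs = pd.DataFrame(rng.standard_normal((n, 4)), columns=[f"o{i}" for i in range(4)])
        outs.insert(0, "dyad_id", range(n))
        bat = run_correlation_battery(feats, outs)
        assert (bat.q >= bat.p - 1e-12).all()
        for _, grp in bat.groupby("stratum"):
            s = grp.sort_values("p")
            assert (np.diff(s.q.to_numpy()) >= -1e-12).all()

    def test_small_strata_skipped(self, rng):
        n = 10
        feats = pd.DataFrame({"dyad_id": range(n), "f": rng.standard_normal(n)})
        outs = pd.DataFrame({"dyad_id": range(n), "o": rng.standard_normal(n)})
        strata = {"tiny": pd.Series([True] * 3 + [False] * 7)}
        bat = run_correlation_battery(feats, outs, strata=strata)
        assert "tiny" not in set(bat.stratum)


class TestLongTableBuilders:
    def test_entropy_long_table_shape(self, rng):
        from dyadflow import feature_names

        n = 12
        feats = pd.DataFrame(
            rng.standard_normal((n, 50)), columns=feature_names()
        )
        feats.insert(0, "dyad_id", [f"D{i}" for i in range(n)])
        cohort = pd.DataFrame(
            {
                "dyad_id": [f"D{i}" for i in range(n)],
                "group": ["control", "stressed"] * 6,
                "sex": ["female", "male"] * 6,
            }
        )
        long = build_entropy_long_table(feats, cohort, "er")
        assert len(long) == n * 20  # 2 signals x 5 paradigms x 2 summaries
        assert set(long.paradigm.unique()) == set(PARADIGMS)

    def test_fraction_long_table_shape(self):
        ep = pd.DataFrame(
            {
                "dyad_id": ["D0", "D0"],
                "hr_source": ["mhr", "fhr"],
                "accel_fraction_time": [0.51, 0.52],
                "decel_fraction_time": [0.48, 0.46],
            }
        )
        cohort = pd.DataFrame(
            {"dyad_id": ["D0"], "group": ["control"], "sex": ["female"]}
        )
        long = build_fraction_long_table(ep, cohort)
        assert len(long) == 4
        assert set(long.event_type) == {"accel", "decel"}
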