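"""k-NN entropy estimators, conditioning mechanics and feature reduction."""

import numpy as np
import pytest

from dyadflow import (
    EntropyParams,
    HRSeries,
    ScaleGrid,
    SimConfig,
    PreparedDyad,
    compute_features,
    entropy_rate,
    feature_names,
    generate_dyad,
    knn_entropy,
    label_epochs,
    net_transfer_entropy,
    sample_entropy,
    surrogate_correction,
    transfer_entropy,
)
from dyadflow.infotheory import _summarize
from dyadflow.preprocess import moving_average

GAUSS_H = 0.5 * np.log(2 * np.pi * np.e)  # 1.4189 nats


def as_series(values, valid=None, fs=1.0, tau=1.0):
    v = np.asarray(values, float)
    if valid is None:
        valid = np.ones(len(v), bool)
    return HRSeries(fs=fs, t0=0.0, values=v, valid=valid, tau=tau)


def ar1(n, phi, rng, sigma_innov=1.0):
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -phi], sigma_innov * rng.standard_normal(n))


def sampen_bruteforce(x, m, r):
    """Exhaustive O(n^2) template counting with Chebyshev distance."""
    n = len(x)
    B = A = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return -np.log(A / B)


class TestKnnEntropy:
    def test_gaussian_closed_form(self, rng):
        h = knn_entropy(rng.standard_normal(10_000), k=5)
        assert h == pytest.approx(GAUSS_H, abs=0.05)

    def test_uniform_closed_form(self, rng):
        h = knn_entropy(rng.uniform(size=10_000), k=5)
        assert h == pytest.approx(0.0, abs=0.05)

    def test_scaling_law(self, rng):
        x = rng.standard_normal(5_000)
        assert knn_entropy(3 * x, k=5) - knn_entropy(x, k=5) == pytest.approx(
            np.log(3), abs=0.02
        )

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            knn_entropy(rng.standard_normal(5), k=5)

    def test_degenerate_dimension_flagged(self, rng):
        pts = np.column_stack([rng.standard_normal(500), np.zeros(500)])
        with pytest.warns(UserWarning, match="zero-variance"):
            knn_entropy(pts, k=5)


class TestEntropyRate:
    def test_iid_equals_marginal_entropy(self, rng):
        x = as_series(rng.standard_normal(20_000))
        p = EntropyParams(max_vectors=25_000)
        assert entropy_rate(x, p).value == pytest.approx(GAUSS_H, abs=0.05)

    def test_gaussian_ar1_closed_form(self, rng):
        phi = 0.6
        x = as_series(ar1(20_000, phi, rng))
        sigma2 = np.var(x.values)
        expected = 0.5 * np.log(2 * np.pi * np.e * sigma2 * (1 - phi**2))
        p = EntropyParams(max_vectors=25_000)
        assert entropy_rate(x, p).value == pytest.approx(expected, abs=0.05)

    def test_insufficient_pairs_reported(self, rng):
        x = as_series(rng.standard_normal(50))
        est = entropy_rate(x, EntropyParams(min_vectors=100))
        assert np.isnan(est.value) and est.reason is not None


class TestSampleEntropy:
    def test_toy_series_matches_bruteforce_exactly(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2], float)
        est = sample_entropy(as_series(x), EntropyParams(min_vectors=2))
        assert est.value == sampen_bruteforce(x, 1, 0.3 * np.std(x))

    def test_random_series_matches_bruteforce_exactly(self, rng):
        x = rng.standard_normal(150)
        est = sample_entropy(as_series(x), EntropyParams(min_vectors=2))
        assert est.value == pytest.approx(
            sampen_bruteforce(x, 1, 0.2 * np.std(x)), abs=1e-12
        )

    def test_constant_series_is_zero(self):
        est = sample_entropy(as_series(np.full(300, 5.0)), EntropyParams(min_vectors=2))
        assert est.value == 0.0

    def test_periodic_series_is_regular(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 7)
        est = sample_entropy(as_series(x), EntropyParams(min_vectors=2))
        assert est.value == pytest.approx(0.0, abs=1e-9)


class TestTransferEntropy:
    @staticmethod
    def coupled_pair(rng, n=20_000, a=0.6, c=0.4):
        x = np.zeros(n)
        y = np.zeros(n)
        ex = rng.standard_normal(n)
        ey = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + ex[t]
            y[t] = a * y[t - 1] + c * x[t - 1] + ey[t]
        return x, y

    @staticmethod
    def granger_te(x, y):
        """Gaussian TE oracle: 0.5 ln(Var(y+|y) / Var(y+|y, x))."""
        Y1, Y0, X0 = y[1:], y[:-1], x[:-1]

        def cond_var(target, preds):
            A = np.column_stack(preds + [np.ones(len(target))])
            beta, *_ = np.linalg.lstsq(A, target, rcond=None)
            return np.var(target - A @ beta)

        return 0.5 * np.log(cond_var(Y1, [Y0]) / cond_var(Y1, [Y0, X0]))

    def test_matches_gaussian_granger_oracle(self, rng):
        x, y = self.coupled_pair(rng)
        oracle = self.granger_te(x, y)
        p = EntropyParams(max_vectors=25_000)
        est = transfer_entropy(as_series(x), as_series(y), p)
        assert abs(est.value - oracle) / oracle < 0.10

    def test_independent_pair_near_zero(self, rng):
        x = as_series(ar1(6_000, 0.5, rng))
        y = as_series(ar1(6_000, 0.5, rng))
        p = EntropyParams(n_surrogates=10, max_vectors=8_000)
        est = surrogate_correction(x, y, p)
        assert abs(est.value) < 0.01

    def test_direction_asymmetry_for_unidirectional_coupling(self, rng):
        x, y = self.coupled_pair(rng, n=15_000)
        p = EntropyParams(max_vectors=20_000)
        fwd = transfer_entropy(as_series(x), as_series(y), p).value
        back = transfer_entropy(as_series(y), as_series(x), p).value
        assert fwd > back

    def test_net_te_triangle_inequality(self, rng):
        x, y = self.coupled_pair(rng, n=5_000)
        p = EntropyParams(n_surrogates=4, max_vectors=6_000)
        mf, fm, net = net_transfer_entropy(as_series(x), as_series(y), p)
        assert abs(net.value) <= abs(mf.value) + abs(fm.value) + 1e-12

    def test_grid_mismatch_rejected(self, rng):
        x = as_series(rng.standard_normal(100))
        y = as_series(rng.standard_normal(101))
        with pytest.raises(ValueError):
            transfer_entropy(x, y)


class TestConditioning:
    def test_conditioned_estimates_use_fewer_vectors(self, prepared, fast_params):
        tau = 1.0
        ff = moving_average(prepared.fhr, tau)
        mf = moving_average(prepared.mhr, tau)
        mask = label_epochs(mf)
        full = entropy_rate(ff, fast_params)
        cond = entropy_rate(ff, fast_params, condition=(mask, "decel"))
        assert cond.n < full.n
        assert np.isfinite(cond.value)

    def test_windows_never_cross_epoch_boundaries(self):
        # one accel run of 6 samples then one decel run; with lag 4 only
        # bases fully inside one event survive
        vals = np.concatenate([np.arange(7.0), np.arange(7.0)[::-1][1:]])
        x = HRSeries(fs=1.0, t0=0.0, values=vals, valid=np.ones(len(vals), bool), tau=4.0)
        mask = label_epochs(x)
        est = transfer_entropy(x, x, EntropyParams(min_vectors=1, k_neighbors=1),
                               condition=(mask, "accel"))
        # accel event has 6 samples; windows of span 4 leave 2 bases
        assert est.n <= 2 or np.isnan(est.value)


class TestFeatureReduction:
    def test_feature_name_scheme(self):
        names = feature_names()
        assert len(names) == 50
        assert len([n for n in names if n.startswith("er_")]) == 20
        assert len([n for n in names if n.startswith("se_")]) == 20
        assert len([n for n in names if n.startswith("net_te_")]) == 10

    def test_constant_curve_summaries(self):
        grid = ScaleGrid(taus=(0.5, 1.0, 2.5))
        vmax, auc = _summarize([0.5, 1.0, 2.5], [2.0, 2.0, 2.0], grid)
        assert vmax == auc == 2.0

    def test_linear_curve_summaries(self):
        grid = ScaleGrid(taus=(0.5, 1.5, 2.5))
        vmax, auc = _summarize([0.5, 1.5, 2.5], [1.0, 2.0, 3.0], grid)
        assert vmax == 3.0 and auc == 2.0

    def test_out_of_band_points_ignored(self):
        grid = ScaleGrid(taus=(0.1, 1.0, 10.0))
        vmax, auc = _summarize([0.1, 1.0, 10.0], [9.0, 2.0, 9.0], grid)
        assert vmax == auc == 2.0

    def test_full_feature_vector(self, prepared, fast_params, small_grid):
        res = compute_features(prepared, small_grid, fast_params)
        assert set(res.features) == set(feature_names())
        finite = sum(np.isfinite(v) for v in res.features.values())
        assert finite >= 45  # short fixture may miss a sparse conditioned cell
        assert set(res.curves.metric.unique()) >= {"er", "se", "net_te"}

    def test_missing_curves_propagate_with_reason(self):
        rec = generate_dyad(SimConfig(duration=60.0), seed=3)
        prep = PreparedDyad.from_recording(rec)
        params = EntropyParams(min_vectors=10_000, n_surrogates=2)
        res = compute_features(prep, ScaleGrid(taus=(1.0,)), params)
        assert all(not np.isfinite(v) for v in res.features.values())
        assert len(res.missing) == 50
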