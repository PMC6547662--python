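"""NIPALS PLS: oracle equivalences, cross-validation, component selection."""

import numpy as np
import pytest

from foliarnirs.pls import (
    CvCurve,
    PlsModel,
    cross_validate,
    fit_pls,
    select_components,
)


class TestFitPls:
    def test_single_component_exact_when_y_is_one_direction(self, rng):
        w = rng.normal(size=12)
        T = rng.normal(size=30)
        X = np.outer(T, w)
        y = 2.0 * T + 1.0
        model = fit_pls(X, y, k=1)
        np.testing.assert_allclose(model.predict_matrix(X), y, atol=1e-10)

    def test_univariate_matches_simple_regression(self, rng):
        x = rng.normal(size=25)
        y = 1.7 * x + 0.3 + rng.normal(0, 0.1, 25)
        model = fit_pls(x[:, None], y, k=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        np.testing.assert_allclose(model.predict_matrix(x[:, None]),
                                   slope * x + intercept, atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        # with k = rank, PLS1 reproduces the normal-equations least-squares fit
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_pls(X, y, k=5)
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(model.predict_matrix(X), Xd @ beta, atol=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 15))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(0, 0.2, 40)
        ours = fit_pls(X, y, k=4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.predict_matrix(X), ref.predict(X).ravel(), atol=1e-8)

    def test_mean_spectrum_predicts_mean_content(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        model = fit_pls(X, y, k=3)
        assert model.predict_matrix(X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10)

    def test_training_r2_nondecreasing_in_k(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        sse = []
        for k in range(1, 7):
            model = fit_pls(X, y, k=k)
            sse.append(np.sum((model.predict_matrix(X) - y) ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(sse, sse[1:]))

    def test_k_above_rank_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 2
        y = X[:, 0] + 0.1
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, k=3)

    def test_extrapolation_warning(self, rng):
        X = rng.normal(size=(20, 4))
        y = X @ np.ones(4)
        model = fit_pls(X, y, k=4)
        with pytest.warns(UserWarning, match="extrapolation"):
            model.predict_matrix(X + 100.0)

    def test_save_load_predicts_bit_identically(self, tmp_path, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        model = fit_pls(X, y, k=3, constituent="N")
        before = model.predict_matrix(X)
        path = tmp_path / "model.json"
        model.save(path)
        clone = PlsModel.load(path)
        np.testing.assert_array_equal(before, clone.predict_matrix(X))


class TestCrossValidate:
    def test_constant_y_gives_zero_rmsecv(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(24, 6))
        curve = cross_validate(X, np.full(24, 3.3), k_max=4, folds=4, seed=1)
        np.testing.assert_allclose(curve.rmsecv, 0.0, atol=1e-12)

    def test_fold_sizes_differ_by_at_most_one(self, rng):
        X = rng.normal(size=(47, 5))
        y = rng.normal(size=47)
        curve = cross_validate(X, y, k_max=3, folds=10, seed=2)
        sizes = [f.size for f in curve.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 47

    def test_grouped_folding_prevents_duplicate_leakage(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] + rng.normal(0, 1.0, 40)
        base = cross_validate(X, y, k_max=3, folds=5, seed=3)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        groups = np.concatenate([np.arange(40), np.arange(40)])
        grouped = cross_validate(X2, y2, k_max=3, folds=5, seed=3, groups=groups)
        # duplicates kept together: error stays near the honest level, far from 0
        assert grouped.rmsecv.min() > 0.5 * base.rmsecv.min()

    def test_rmsecv_near_noise_floor(self, rng):
        sigma = 0.3
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, sigma, 30)
        curve = cross_validate(X, y, k_max=5, folds=10, seed=4)
        assert 0.7 * sigma <= curve.rmsecv.min() <= 1.5 * sigma

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        a = cross_validate(X, y, k_max=5, folds=10, seed=42)
        b = cross_validate(X, y, k_max=5, folds=10, seed=42)
        np.testing.assert_array_equal(a.rmsecv, b.rmsecv)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_infeasible_k_max_lowered_with_warning(self, rng):
        X = rng.normal(size=(12, 20))
        y = rng.normal(size=12)
        with pytest.warns(UserWarning, match="lowered"):
            curve = cross_validate(X, y, k_max=15, folds=4, seed=5)
        assert curve.k_max < 15


class TestSelectComponents:
    def test_within_tolerance_of_minimum(self):
        curve = CvCurve(ks=np.arange(1, 6), rmsecv=np.array([5, 3, 1, 1.001, 0.999]),
                        r2_cval=np.zeros(5), folds=[], k_max=5)
        assert select_components(curve, tolerance=0.02) == 3

    def test_zero_tolerance_takes_argmin(self):
        curve = CvCurve(ks=np.arange(1, 5), rmsecv=np.array([4.0, 3.0, 2.0, 1.0]),
                        r2_cval=np.zeros(4), folds=[], k_max=4)
        assert select_components(curve, tolerance=0.0) == 4

    def test_flat_curve_prefers_parsimony(self):
        curve = CvCurve(ks=np.arange(1, 5), rmsecv=np.ones(4),
                        r2_cval=np.zeros(4), folds=[], k_max=4)
        assert select_components(curve) == 1
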