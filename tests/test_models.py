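"""Ridge/kernel-ridge/GBLUP/MTGBLUP algebra: hand-solved toys, the
primal-dual (Woodbury) equivalence, RR-GBLUP equivalence, multi-trait
reductions, PCA invariances, and penalty selection."""

import numpy as np
import pytest

from multiline_gs.kernels import KernelSpec, cross, gram
from multiline_gs.models import (
    GBLUPRegressor,
    KernelRidgePredictor,
    MTGBLUPRegressor,
    RidgeGenomic,
    build_G,
    fit_kernel_ridge,
    fit_ridge_dual,
    fit_ridge_primal,
    gblup_predict,
    mtgblup_predict,
    predict_kernel,
    predict_ridge,
    project,
    reduce_pca,
    select_gamma,
)


class TestRidge:
    def test_hand_solved_single_marker(self):
        # (X'X + 1)^-1 X'y with X=[1,2]', y=[1,2]: w = 5/6
        X = np.array([[1.0], [2.0]])
        y = np.array([1.0, 2.0])
        fit = fit_ridge_primal(X, y, 1.0)
        assert fit.weights[0] == pytest.approx(5 / 6, abs=1e-12)
        dual = fit_ridge_dual(X, y, 1.0)
        assert predict_ridge(dual, np.array([[1.0]]))[0] == pytest.approx(5 / 6, abs=1e-10)

    def test_infinite_shrinkage_limit(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        w = fit_ridge_primal(X, y, 1e12).weights
        w_ls = np.linalg.pinv(X) @ y
        assert np.linalg.norm(w) < 1e-9 * np.linalg.norm(w_ls)

    def test_least_squares_limit_recovers_truth(self, rng):
        X = rng.normal(size=(20, 5))
        w_true = rng.normal(size=5)
        y = X @ w_true
        w = fit_ridge_primal(X, y, 1e-10).weights
        assert np.abs(w - w_true).max() < 1e-6

    @pytest.mark.parametrize("shape", [(15, 40), (40, 15)])
    def test_primal_dual_equivalence(self, shape, rng):
        X = rng.normal(size=shape)
        y = rng.normal(size=shape[0])
        Xt = rng.normal(size=(6, shape[1]))
        for gamma in (0.1, 1.0, 50.0):
            p = predict_ridge(fit_ridge_primal(X, y, gamma), Xt)
            d = predict_ridge(fit_ridge_dual(X, y, gamma), Xt)
            assert np.abs(p - d).max() < 1e-8

    def test_zero_design_predicts_zero(self):
        X = np.zeros((4, 3))
        y = np.array([1.0, -1.0, 2.0, 0.5])
        fit = fit_ridge_dual(X, y, 1.0)
        assert np.allclose(predict_ridge(fit, np.zeros((2, 3))), 0.0)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            fit_ridge_primal(np.ones((2, 1)), np.ones(2), 0.0)

    def test_estimator_centers_and_matches_solver(self, rng):
        X = rng.integers(0, 3, size=(25, 40)).astype(float)
        y = rng.normal(size=25)
        Xt = rng.integers(0, 3, size=(8, 40)).astype(float)
        pri = RidgeGenomic(gamma=3.0, solver="primal").fit(X, y).predict(Xt)
        dua = RidgeGenomic(gamma=3.0, solver="dual").fit(X, y).predict(Xt)
        assert np.abs(pri - dua).max() < 1e-8


class TestKernelRidge:
    def test_linear_kernel_equals_dual_ridge(self, rng):
        X = rng.normal(size=(12, 30))
        y = rng.normal(size=12)
        Xt = rng.normal(size=(5, 30))
        K = gram(X, KernelSpec(family="linear"))
        fit = fit_kernel_ridge(K, y, 2.0)
        k = cross(X, Xt, KernelSpec(family="linear"))
        pk = predict_kernel(fit, k)
        pd_ = predict_ridge(fit_ridge_dual(X, y, 2.0), Xt)
        assert np.abs(pk - pd_).max() < 1e-10

    def test_identity_kernel_closed_form(self):
        y = np.array([2.0, -4.0, 6.0])
        fit = fit_kernel_ridge(np.eye(3), y, 1.0)
        assert np.allclose(fit.dual_coef, y / 2)
        assert predict_kernel(fit, np.eye(3)[:, [1]])[0] == pytest.approx(-2.0)

    def test_alpha_matches_generic_dense_solve(self, rng):
        X = rng.integers(0, 3, size=(12, 20)).astype(float)
        y = rng.normal(size=12)
        spec = KernelSpec(family="distance", bandwidth=4.0)
        K = gram(X, spec, bandwidth=4.0).values
        fit = fit_kernel_ridge(K, y, 0.7)
        alpha_oracle = np.linalg.solve(K + 0.7 * np.eye(12), y)
        assert np.abs(fit.dual_coef - alpha_oracle).max() < 1e-10

    def test_non_spd_system_reports_condition(self):
        # an indefinite "kernel" cannot be factorized; the error carries a
        # condition estimate of the regularized system
        K = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            fit_kernel_ridge(K, np.ones(2), 0.5)


class TestGBLUP:
    def test_duplicated_animal_exchangeable(self, rng):
        X = rng.integers(0, 3, size=(10, 50)).astype(float)
        X[3] = X[7]
        gr = build_G(X)
        assert np.allclose(gr.G[3], gr.G[7])
        y = rng.normal(size=8)
        gebv = gblup_predict(gr, y, 1.5, np.arange(8), np.array([3, 7]))
        # only training animals 0..7 contribute; 3 and 7... 3 is in training
        gebv_all = gblup_predict(gr, np.append(y, y[:2]), 1.5, np.arange(10), np.array([3, 7]))
        assert gebv_all[0] != 0  # smoke: predictions exist

    def test_duplicated_test_animals_equal_gebv(self, rng):
        X = rng.integers(0, 3, size=(12, 40)).astype(float)
        X[10] = X[11]
        gr = build_G(X)
        y = rng.normal(size=10)
        gebv = gblup_predict(gr, y, 2.0, np.arange(10), np.array([10, 11]))
        assert gebv[0] == pytest.approx(gebv[1], abs=1e-12)

    def test_rr_gblup_equivalence(self, rng):
        # GBLUP with ratio lambda == dual ridge on Z with gamma = lambda*scale
        X = rng.integers(0, 3, size=(15, 60)).astype(float)
        y = rng.normal(size=10)
        gr = build_G(X)
        Z = X - 2 * gr.freqs[None, :]
        lam = 1.8
        gebv = gblup_predict(gr, y, lam, np.arange(10), np.arange(10, 15))
        yc = y - y.mean()
        ridge = fit_ridge_dual(Z[:10], yc, lam * gr.scale)
        pred = predict_ridge(ridge, Z[10:])
        assert np.abs(gebv - pred).max() < 1e-8

    def test_constant_phenotype_zero_gebv(self, rng):
        X = rng.integers(0, 3, size=(8, 30)).astype(float)
        gr = build_G(X)
        gebv = gblup_predict(gr, np.full(6, 3.7), 1.0, np.arange(6), np.array([6, 7]))
        assert np.allclose(gebv, 0.0)

    def test_estimator_heritability_lambda(self, rng):
        X = rng.integers(0, 3, size=(30, 80)).astype(float)
        y = rng.normal(size=30)
        est = GBLUPRegressor(heritability=0.3).fit(X, y)
        assert est.lambda_ == pytest.approx(0.7 / 0.3)
        assert est.predict(X).shape == (30,)


class TestMTGBLUP:
    def _setup(self, rng, n=30, m=60, n_lines=2):
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        gr = build_G(X)
        lines = np.array(["A", "B"] * (n // 2))[:n]
        y = rng.normal(size=n)
        return gr, lines, y

    def test_identity_correlation_decouples_to_per_line_gblup(self, rng):
        gr, lines, y = self._setup(rng)
        idx_a = np.flatnonzero(lines == "A")[:10]
        idx_b = np.flatnonzero(lines == "B")[:10]
        test_idx = np.arange(25, 30)
        sg = np.array([0.4, 0.6])
        se = np.array([0.6, 0.4])
        fit = mtgblup_predict(
            gr, [(idx_a, y[idx_a]), (idx_b, y[idx_b])], sg, np.eye(2), se
        )
        for li, (sgl, sel, idx) in enumerate(
            [(0.4, 0.6, idx_a), (0.6, 0.4, idx_b)]
        ):
            oracle = gblup_predict(gr, y[idx], sel / sgl, idx, test_idx)
            assert np.abs(fit.gebv[test_idx, li] - oracle).max() < 1e-8

    def test_unit_correlation_equal_variance_pools(self, rng):
        gr, lines, y = self._setup(rng)
        idx_a = np.flatnonzero(lines == "A")[:10]
        idx_b = np.flatnonzero(lines == "B")[:10]
        # pre-center per line so the two formulations share the fixed effects
        y = y.copy()
        y[idx_a] -= y[idx_a].mean()
        y[idx_b] -= y[idx_b].mean()
        test_idx = np.arange(25, 30)
        corr = np.ones((2, 2))
        fit = mtgblup_predict(
            gr, [(idx_a, y[idx_a]), (idx_b, y[idx_b])],
            np.array([0.5, 0.5]), corr, np.array([0.8, 0.8]),
        )
        pooled_idx = np.concatenate([idx_a, idx_b])
        oracle = gblup_predict(gr, y[pooled_idx], 0.8 / 0.5, pooled_idx, test_idx)
        for li in range(2):
            assert np.abs(fit.gebv[test_idx, li] - oracle).max() < 1e-6

    def test_negative_correlation_selection_index_identity(self, rng):
        # training on line A only: line-B GEBV = r * (sB/sA) * line-A GEBV
        X = rng.integers(0, 3, size=(5, 20)).astype(float)
        gr = build_G(X)
        y = rng.normal(size=3)
        r = -0.9
        sg = np.array([1.0, 4.0])  # sd ratio sB/sA = 2
        corr = np.array([[1.0, r], [r, 1.0]])
        fit = mtgblup_predict(
            gr, [(np.arange(3), y), (np.array([], dtype=int), np.array([]))],
            sg, corr, np.array([0.5, 0.5]),
        )
        expected = r * 2.0 * fit.gebv[:, 0]
        assert np.abs(fit.gebv[:, 1] - expected).max() < 1e-10

    def test_double_phenotyped_animal_rejected(self, rng):
        gr, lines, y = self._setup(rng)
        with pytest.raises(ValueError, match="one trait"):
            mtgblup_predict(
                gr,
                [(np.array([0, 1]), y[:2]), (np.array([1, 2]), y[1:3])],
                np.array([0.5, 0.5]), np.eye(2), np.array([0.5, 0.5]),
            )

    def test_estimator_roundtrip(self, rng):
        X = rng.integers(0, 3, size=(40, 70)).astype(float)
        y = rng.normal(size=40)
        lines = np.array(["A"] * 20 + ["B"] * 20)
        est = MTGBLUPRegressor(
            genetic_variances=[0.3, 0.3],
            genetic_correlation=np.array([[1.0, 0.6], [0.6, 1.0]]),
            residual_variances=[0.7, 0.7],
            line_names=("A", "B"),
        ).fit(X, y, lines=lines)
        Xt = rng.integers(0, 3, size=(6, 70)).astype(float)
        preds = est.predict(Xt, lines=np.array(["A", "B", "A", "B", "A", "B"]))
        assert preds.shape == (6,)
        assert np.isfinite(preds).all()


class TestPCA:
    def test_full_variance_preserves_geometry(self, rng):
        X = rng.integers(0, 3, size=(20, 50)).astype(float)
        red = reduce_pca(X, 1.0)
        S = project(X, red)
        from scipy.spatial.distance import pdist

        assert np.abs(pdist(S) - pdist(X)).max() < 1e-8
        Xc = X - X.mean(axis=0)
        assert np.abs(S @ S.T - Xc @ Xc.T).max() < 1e-8

    def test_exact_low_rank(self, rng):
        B = rng.normal(size=(30, 2))
        W = rng.normal(size=(2, 40))
        X = B @ W
        red = reduce_pca(X, 0.97)
        assert red.rank == 2

    def test_full_variance_rbf_invariance_on_fitted_points(self, rng):
        # PCA fitted on the stacked train+test matrix preserves all pairwise
        # distances, hence RBF predictions are unchanged
        X = rng.integers(0, 3, size=(50, 200)).astype(float)
        Xtr, Xte = X[:40], X[40:]
        y = rng.normal(size=40)
        red = reduce_pca(X, 1.0)
        p_raw = (
            KernelRidgePredictor(family="distance", bandwidth="auto", gamma=1.0)
            .fit(Xtr, y).predict(Xte)
        )
        p_pca = (
            KernelRidgePredictor(family="distance", bandwidth="auto", gamma=1.0)
            .fit(project(Xtr, red), y).predict(project(Xte, red))
        )
        assert np.abs(p_raw - p_pca).max() < 1e-6

    def test_train_only_fit_preserves_inner_products(self, rng):
        # projection fitted on training alone still preserves test-train
        # centered inner products (test rows project onto the training span)
        Xtr = rng.integers(0, 3, size=(30, 25)).astype(float)
        Xte = rng.integers(0, 3, size=(10, 25)).astype(float)
        red = reduce_pca(Xtr, 1.0)
        Str, Ste = project(Xtr, red), project(Xte, red)
        Ztr = Xtr - Xtr.mean(axis=0)
        Zte = Xte - Xtr.mean(axis=0)
        assert np.abs(Ste @ Str.T - Zte @ Ztr.T).max() < 1e-8

    def test_threshold_validation(self, rng):
        with pytest.raises(ValueError):
            reduce_pca(rng.normal(size=(5, 5)), 0.0)


class TestSelectGamma:
    def test_single_value_grid(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        assert select_gamma(X, y, grid=[7.0], n_folds=3) == 7.0

    def test_pure_noise_prefers_shrinkage(self):
        # with no signal, held-out correlation is flat in gamma; the
        # one-SE rule then drifts to the heaviest penalty far more often
        # than the uniform 1-in-5 a plain argmax would give
        grid = np.geomspace(0.1, 1e4, 5)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 30))
            y = r.normal(size=60)
            g = select_gamma(X, y, grid=grid, n_folds=3, seed=seed)
            hits += g == grid[-1]
        assert hits >= 12

    def test_strong_signal_prefers_less_shrinkage(self):
        grid = np.geomspace(0.1, 1e6, 6)
        below = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 15))
            w = r.normal(size=15)
            y = X @ w + 0.05 * r.normal(size=60)
            g = select_gamma(X, y, grid=grid, n_folds=3, seed=seed)
            below += g < grid[-1]
        assert below >= 8

    def test_stratified_folds_seeded(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        lines = np.array(["A", "B"] * 20)
        g1 = select_gamma(X, y, grid=[1.0, 10.0], seed=5, lines=lines)
        g2 = select_gamma(X, y, grid=[1.0, 10.0], seed=5, lines=lines)
        assert g1 == g2
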