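"""Model fitting: baselines, screening, block updates, geQTL variants."""

import numpy as np
import pytest
from scipy import optimize, stats

from geqtl import (
    FitOptions,
    build_projector,
    fit_geqtl,
    fit_lasso,
    fit_lors,
    geqtl_loss,
    objective,
    screen,
    standardize,
    svt,
    update_C_ridge,
    update_L,
)
from geqtl.models import update_A, update_B, update_C_l1
from geqtl.solvers import solve_l1_ls


def _lasso_objective(W, X, Z, eta):
    R = Z - W @ X
    return float(np.sum(R * R)) + eta * float(np.abs(W).sum())


class TestFitLasso:
    def test_zero_penalty_equals_least_squares(self, rng):
        X = rng.normal(size=(4, 30))
        Z = rng.normal(size=(3, 30))
        W = fit_lasso(X, Z, 0.0).W
        W_ols = Z @ X.T @ np.linalg.inv(X @ X.T)
        np.testing.assert_allclose(W, W_ols, atol=1e-6)

    def test_penalty_above_subgradient_bound_zeroes_solution(self, rng):
        X = standardize(rng.normal(size=(5, 25)))
        Z = standardize(rng.normal(size=(4, 25)))
        eta = 2.0 * np.abs(Z @ X.T).max() * 1.01
        assert not fit_lasso(X, Z, eta).W.any()

    def test_matches_proximal_gradient_oracle(self, rng):
        """Coordinate descent (sklearn) and our FISTA solver attack the
        same convex objective; their optima must agree."""
        X = rng.normal(size=(6, 20))
        Z = rng.normal(size=(4, 20))
        eta = 0.5
        W_cd = fit_lasso(X, Z, eta, max_iter=50000).W
        W_pg = solve_l1_ls(Z, X, eta, np.zeros((4, 6)), max_iter=20000, tol=1e-16)
        f_cd = _lasso_objective(W_cd, X, Z, eta)
        f_pg = _lasso_objective(W_pg, X, Z, eta)
        assert abs(f_cd - f_pg) <= 1e-6 * max(f_cd, 1.0)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_lasso(np.ones((2, 5)), np.ones((2, 5)), -1.0)


class TestFitLors:
    def test_huge_rho_reduces_to_lasso(self, rng):
        X = standardize(rng.normal(size=(5, 20)))
        Z = standardize(rng.normal(size=(4, 20)))
        m = fit_lors(X, Z, 0.3, rho=1e6)
        assert not m.L.any()
        np.testing.assert_allclose(m.W, fit_lasso(X, Z, 0.3).W, atol=1e-10)

    def test_huge_eta_leaves_svt_of_Z(self, rng):
        X = standardize(rng.normal(size=(5, 20)))
        Z = standardize(rng.normal(size=(4, 20)))
        m = fit_lors(X, Z, eta=1e6, rho=0.4)
        assert not m.W.any()
        np.testing.assert_allclose(m.L, svt(Z, 0.2), atol=1e-12)

    def test_objective_no_worse_than_lasso_alone(self, small_std):
        X, Z, _ = small_std
        m = fit_lors(X, Z, 0.2, 0.5)
        lasso_only = fit_lasso(X, Z, 0.2)
        lasso_obj = _lasso_objective(lasso_only.W, X, Z, 0.2)
        assert m.objective_trace[-1] <= lasso_obj + 1e-9

    def test_trace_monotone(self, small_std):
        X, Z, _ = small_std
        m = fit_lors(X, Z, 0.2, 0.5)
        diffs = np.diff(m.objective_trace)
        assert np.all(diffs <= 1e-9 * np.abs(m.objective_trace[:-1]))


class TestScreen:
    def test_perfectly_correlated_pair_always_masked_in(self, rng):
        X = standardize(rng.normal(size=(3, 30)))
        Z = np.vstack([X[0], standardize(rng.normal(size=(1, 30)))[0]])
        mask = screen(X, Z, pvalue=1e-8)
        assert mask.R[0, 0] == 1

    def test_pvalue_one_gives_all_ones(self, rng):
        X = standardize(rng.normal(size=(4, 20)))
        Z = standardize(rng.normal(size=(3, 20)))
        assert screen(X, Z, pvalue=1.0).R.all()

    def test_threshold_matches_per_pair_regression_pvalues(self, rng):
        """The correlation threshold must reproduce per-pair simple
        regression tests: masked-in iff the pair's t-test p-value is
        below the requested level."""
        H, p = 50, 0.01
        X = standardize(rng.normal(size=(5, H)))
        Z = standardize(rng.normal(size=(5, H)) + 0.5 * X)
        mask = screen(X, Z, pvalue=p)
        for i in range(5):
            for j in range(5):
                r, pv = stats.pearsonr(Z[i], X[j])
                assert mask.R[i, j] == (1 if pv < p else 0), (i, j, pv)

    def test_tiny_sample_count_rejected(self, rng):
        with pytest.raises(ValueError, match="H > 3"):
            screen(np.ones((2, 3)), np.ones((2, 3)), 0.05)


class TestProjector:
    def test_selects_set_bits(self):
        P = build_projector(np.array([1, 0, 1]))
        assert P.shape == (3, 2)
        np.testing.assert_array_equal(P.T @ P, np.eye(2))
        np.testing.assert_array_equal(P @ P.T, np.diag([1.0, 0.0, 1.0]))

    def test_full_mask_is_identity(self):
        np.testing.assert_array_equal(build_projector(np.ones(4)), np.eye(4))

    def test_empty_mask(self, rng):
        P = build_projector(np.zeros(5))
        assert P.shape == (5, 0)
        c = rng.normal(size=(1, 5))
        assert not (c @ P @ P.T).any()


class TestUpdateL:
    def test_zero_rank_residual_gives_zero(self, rng):
        X = rng.normal(size=(3, 8))
        A = rng.normal(size=(2, 3))
        B = rng.normal(size=(4, 2))
        C = rng.normal(size=(4, 3))
        Z = (B @ A + C) @ X
        assert not update_L(Z, A, B, C, X, rho=1.0).any()

    def test_zero_rho_returns_residual(self, rng):
        X = rng.normal(size=(3, 8))
        A = np.zeros((1, 3))
        B = np.zeros((4, 1))
        C = np.zeros((4, 3))
        Z = rng.normal(size=(4, 8))
        np.testing.assert_allclose(update_L(Z, A, B, C, X, 0.0), Z)

    def test_exact_block_minimizer(self, rng):
        """No perturbation of the updated L may lower the objective."""
        X = rng.normal(size=(3, 10))
        A = rng.normal(size=(2, 3))
        B = rng.normal(size=(5, 2))
        C = rng.normal(size=(5, 3))
        Z = rng.normal(size=(5, 10))
        rho = 1.2
        L = update_L(Z, A, B, C, X, rho)

        def f(Lm):
            return geqtl_loss(Z, Lm, A, B, C, X) + rho * np.linalg.svd(
                Lm, compute_uv=False
            ).sum()

        base = f(L)
        for _ in range(10):
            assert f(L + rng.normal(scale=0.05, size=L.shape)) >= base - 1e-9


class TestUpdateCRidge:
    def test_empty_mask_row_gives_zero_row(self, rng):
        X = rng.normal(size=(4, 10))
        Z = rng.normal(size=(3, 10))
        zero = np.zeros
        R = np.ones((3, 4))
        R[1] = 0
        C = update_C_ridge(Z, zero((3, 10)), zero((1, 4)), zero((3, 1)), X, R, 0.5)
        assert not C[1].any()
        assert C[0].any()

    def test_full_mask_matches_textbook_ridge(self, rng):
        X = rng.normal(size=(4, 12))
        Z = rng.normal(size=(3, 12))
        zero = np.zeros
        gamma = 0.7
        C = update_C_ridge(Z, zero((3, 12)), zero((1, 4)), zero((3, 1)), X,
                           np.ones((3, 4)), gamma)
        expected = Z @ X.T @ np.linalg.inv(X @ X.T + gamma * np.eye(4))
        np.testing.assert_allclose(C, expected, atol=1e-10)

    def test_matches_generic_qp_solver(self, rng):
        """Row-wise closed form vs scipy BFGS on the masked quadratic."""
        N, K, H = 4, 6, 9
        X = rng.normal(size=(K, H))
        D = rng.normal(size=(N, H))
        R = (rng.random((N, K)) < 0.5).astype(float)
        gamma = 0.3
        zero = np.zeros
        C = update_C_ridge(D, zero((N, H)), zero((1, K)), zero((N, 1)), X, R, gamma)
        for i in range(N):
            sel = np.flatnonzero(R[i])
            if sel.size == 0:
                assert not C[i].any()
                continue
            Xs = X[sel]

            def f(c):
                r = D[i] - c @ Xs
                return float(r @ r) + gamma * float(c @ c)

            res = optimize.minimize(f, np.zeros(sel.size), method="BFGS",
                                    options={"gtol": 1e-12})
            np.testing.assert_allclose(C[i, sel], res.x, atol=1e-7)

    def test_zero_gamma_rejected(self, rng):
        with pytest.raises(ValueError):
            update_C_ridge(np.ones((2, 3)), np.zeros((2, 3)), np.zeros((1, 2)),
                           np.zeros((2, 1)), np.ones((2, 3)), np.ones((2, 2)), 0.0)


class TestL1Updates:
    def test_huge_penalties_zero_each_block(self, small_std):
        X, Z, _ = small_std
        m = fit_geqtl(X, Z, 2, alpha=1e6, beta=1e6, gamma=1e6, rho=1e6,
                      options=FitOptions(max_sweeps=3))
        assert not m.A.any() and not m.B.any() and not m.C.any() and not m.L.any()

    def test_update_A_matches_vectorized_lasso_oracle(self, rng):
        """With B fixed the A subproblem is a lasso in vec(A): check
        against sklearn on the Kronecker-expanded design."""
        from sklearn.linear_model import Lasso

        N, M, K, H = 3, 1, 4, 15
        X = rng.normal(size=(K, H))
        B = rng.normal(size=(N, M))
        D = rng.normal(size=(N, H))
        alpha = 0.4
        A = update_A(D, np.zeros((N, H)), B, np.zeros((N, K)), X,
                     np.zeros((M, K)), alpha, max_iter=20000)
        # vec over samples/genes: y = vec(D), design[:, j] = vec(B A_j X) basis
        design = np.stack(
            [np.outer(B[:, 0], X[j]).ravel() for j in range(K)], axis=1
        )
        y = D.ravel()
        oracle = Lasso(alpha=alpha / (2 * y.size), fit_intercept=False,
                       max_iter=200000, tol=1e-12).fit(design, y)

        def f(a):
            return float(np.sum((D - B @ a.reshape(1, K) @ X) ** 2)) + alpha * np.abs(a).sum()

        assert f(A.ravel()) <= f(oracle.coef_) * (1 + 1e-8) + 1e-10

    def test_masked_C_update_freezes_zeros(self, rng):
        X = rng.normal(size=(4, 10))
        D = rng.normal(size=(3, 10))
        mask = np.zeros((3, 4))
        mask[0, 1] = 1
        C = update_C_l1(D, np.zeros((3, 10)), np.zeros((1, 4)), np.zeros((3, 1)),
                        X, np.zeros((3, 4)), 0.01, mask=mask)
        outside = C[mask == 0]
        assert not outside.any()
        assert C[0, 1] != 0

    def test_all_zero_mask_keeps_C_zero(self, rng):
        X = rng.normal(size=(4, 10))
        D = rng.normal(size=(3, 10))
        C = update_C_l1(D, np.zeros((3, 10)), np.zeros((1, 4)), np.zeros((3, 1)),
                        X, np.zeros((3, 4)), 0.01, mask=np.zeros((3, 4)))
        assert not C.any()


class TestFitGeqtl:
    def test_noiseless_realizable_reaches_tiny_loss(self, rng):
        K, N, H, M = 12, 10, 20, 2
        X = standardize(np.asarray(rng.binomial(2, 0.4, size=(K, H)), float))
        A0 = rng.normal(size=(M, K))
        B0 = rng.normal(size=(N, M))
        C0 = np.zeros((N, K))
        C0[np.arange(min(N, K)), np.arange(min(N, K))] = 0.5
        Z = (B0 @ A0 + C0) @ X
        m = fit_geqtl(X, Z, M, 1e-6, 1e-6, 1e-6, 1e-6,
                      options=FitOptions(max_sweeps=200, tol=1e-14, inner_max_iter=500))
        assert geqtl_loss(Z, m.L, m.A, m.B, m.C, X) <= 1e-8 * np.sum(Z**2)

    def test_block_trace_monotone(self, small_std):
        X, Z, _ = small_std
        m = fit_geqtl(X, Z, 2, 0.1, 0.1, 0.2, 1.0, options=FitOptions(max_sweeps=8))
        vals = [v for _, v in m.block_trace]
        for prev, cur in zip(vals, vals[1:]):
            assert cur <= prev * (1 + 1e-9) + 1e-12

    def test_gene_permutation_equivariance(self, small_std):
        """Permuting gene order permutes B, C, L rows and leaves the
        objective unchanged (deterministic initialization)."""
        X, Z, _ = small_std
        perm = np.random.default_rng(1).permutation(Z.shape[0])
        opts = FitOptions(max_sweeps=5)
        m1 = fit_geqtl(X, Z, 2, 0.1, 0.1, 0.2, 1.0, options=opts)
        m2 = fit_geqtl(X, Z[perm], 2, 0.1, 0.1, 0.2, 1.0, options=opts)
        assert m1.objective_trace[-1] == pytest.approx(m2.objective_trace[-1], rel=1e-6)
        np.testing.assert_allclose(m2.C, m1.C[perm], atol=1e-6)
        np.testing.assert_allclose(m2.L, m1.L[perm], atol=1e-6)
        np.testing.assert_allclose(m2.B @ m2.A, (m1.B @ m1.A)[perm], atol=1e-6)

    def test_masked_variants_require_mask(self, small_std):
        X, Z, _ = small_std
        with pytest.raises(ValueError, match="mask"):
            fit_geqtl(X, Z, 2, 0.1, 0.1, 0.1, 1.0, variant="geqtl_plus")

    def test_plus_respects_mask_support(self, small_std):
        X, Z, _ = small_std
        mask = screen(X, Z, pvalue=0.05)
        m = fit_geqtl(X, Z, 2, 0.1, 0.1, 0.1, 1.0, variant="geqtl_plus",
                      options=FitOptions(max_sweeps=5), mask=mask)
        assert not m.C[mask.R == 0].any()

    def test_ridge_variant_uses_closed_form_support(self, small_std):
        X, Z, _ = small_std
        mask = screen(X, Z, pvalue=0.05)
        m = fit_geqtl(X, Z, 2, 0.1, 0.1, 0.5, 1.0, variant="geqtl_ridge",
                      options=FitOptions(max_sweeps=5), mask=mask)
        assert not m.C[mask.R == 0].any()
        # ridge never produces exact zeros inside the mask
        inside = m.C[mask.R == 1]
        assert np.mean(inside != 0) > 0.9
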