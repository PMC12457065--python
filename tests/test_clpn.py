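"""Network estimation: standardization contracts, lasso solver oracles
(soft threshold, lambda_max, OLS limit), CV determinism and recovery."""

import numpy as np
import pytest

import trajnet as tn
from trajnet.clpn import (
    LassoConfig,
    ZeroVarianceError,
    cv_select_lambda,
    lambda_max,
    lasso_path_fit,
    standardize_block,
)


class TestStandardize:
    def test_zero_variance_named(self, var_panel):
        panel = var_panel.copy()
        panel["TH_1"] = 1.5
        with pytest.raises(ZeroVarianceError, match="TH_1"):
            standardize_block(panel, panel["id"], (1, 2))

    def test_unit_moments(self, var_panel):
        b = standardize_block(var_panel, var_panel["id"], (1, 2))
        for M in (b.X_t, b.X_t1, b.C):
            np.testing.assert_allclose(M.mean(0), 0.0, atol=1e-12)
            np.testing.assert_allclose(M.std(0), 1.0, atol=1e-12)

    def test_idempotent(self, var_panel):
        b = standardize_block(var_panel, var_panel["id"], (1, 2))
        panel2 = var_panel.copy()
        for j, n in enumerate(tn.NODES):
            panel2[f"{n}_1"] = b.X_t[:, j]
            panel2[f"{n}_2"] = b.X_t1[:, j]
        b2 = standardize_block(panel2, panel2["id"], (1, 2))
        np.testing.assert_allclose(b2.X_t, b.X_t, atol=1e-12)


class TestLassoSolver:
    def test_ols_limit(self, rng):
        X = rng.standard_normal((80, 5))
        y = X @ rng.standard_normal(5) + 0.1 * rng.standard_normal(80)
        coef = lasso_path_fit(X, y, penalty_free=(), lam=0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(coef, ols, atol=1e-6)

    def test_soft_threshold_on_orthonormal_design(self, rng):
        n, p = 64, 4
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)  # X'X = n I, the solver's (1/2n) scaling
        y = rng.standard_normal(n)
        ols = X.T @ y / n
        for lam in (0.05, 0.2, 0.8):
            coef = lasso_path_fit(X, y, penalty_free=(), lam=lam)
            expect = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            np.testing.assert_allclose(coef, expect, atol=1e-6)

    def test_lambda_max_zeroes_everything(self, rng):
        X = rng.standard_normal((100, 6))
        y = rng.standard_normal(100)
        lmax = lambda_max(X, y)
        coef = lasso_path_fit(X, y, lam=lmax * 1.0001)
        assert np.all(coef == 0.0)
        coef2 = lasso_path_fit(X, y, lam=lmax * 0.9)
        assert np.any(coef2 != 0.0)

    def test_penalty_free_columns_unshrunk(self, rng):
        X = rng.standard_normal((200, 4))
        beta = np.array([0.0, 0.0, 0.5, 0.5])
        y = X @ beta + 0.1 * rng.standard_normal(200)
        coef = lasso_path_fit(X, y, penalty_free=(2, 3), lam=10.0)
        assert coef[0] == coef[1] == 0.0
        # unpenalized block solved by least squares given the penalized fit
        assert abs(coef[2] - 0.5) < 0.05 and abs(coef[3] - 0.5) < 0.05

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            lasso_path_fit(np.array([[np.nan, 1.0]]), np.array([1.0]), lam=0.1)

    def test_sparsity_monotone_along_path(self, rng):
        X = rng.standard_normal((120, 8))
        y = X @ np.array([1, 0.5, 0, 0, 0.2, 0, 0, 0.1]) + rng.standard_normal(120)
        lams = np.logspace(np.log10(lambda_max(X, y)), -3, 40)
        nnz = [np.sum(lasso_path_fit(X, y, lam=l) != 0) for l in lams]
        # nonzero count non-increasing in lambda (path runs lambda descending)
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))


class TestCV:
    def test_deterministic_given_fold_seed(self, rng):
        X = rng.standard_normal((100, 6))
        y = X[:, 0] * 0.5 + rng.standard_normal(100)
        cfg = LassoConfig(fold_seed=5)
        assert cv_select_lambda(X, y, cfg) == cv_select_lambda(X, y, cfg)

    def test_noiseless_single_predictor(self, rng):
        X = rng.standard_normal((100, 6))
        y = 0.8 * X[:, 2]
        lam = cv_select_lambda(X, y, LassoConfig(fold_seed=1))
        coef = lasso_path_fit(X, y, lam=lam)
        assert coef[2] != 0.0
        assert np.sum(coef != 0.0) <= 2  # essentially only the true predictor

    def test_pure_noise_1se_selects_empty(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((150, 6))
            y = rng.standard_normal(150)
            lam = cv_select_lambda(X, y, LassoConfig(lambda_rule="1se", fold_seed=s))
            coef = lasso_path_fit(X, y, lam=lam)
            hits += int(np.all(coef == 0.0))
        assert hits >= 9

    def test_too_few_subjects(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="n_folds"):
            cv_select_lambda(X, X[:, 0], LassoConfig(n_folds=10))


class TestFitCLPN:
    def test_null_network_mostly_empty(self):
        zeros = 0
        total = 0
        for s in range(3):
            spec = tn.CrossLagSpec(n_subjects=400, transition=np.zeros((6, 6)), seed=200 + s)
            panel = tn.generate_var_panel(spec)
            net = tn.fit_clpn(
                panel, panel["id"], (1, 2), LassoConfig(lambda_rule="1se", fold_seed=s)
            )
            off = net.W[~np.eye(6, dtype=bool)]
            zeros += np.sum(off == 0.0)
            total += off.size
        assert zeros / total >= 0.9

    def test_scale_invariance_through_standardization(self, var_panel):
        cfg = LassoConfig(fold_seed=3)
        net = tn.fit_clpn(var_panel, var_panel["id"], (1, 2), cfg)
        scaled = var_panel.copy()
        for c in [f"{n}_1" for n in tn.NODES] + ["age"]:
            scaled[c] = scaled[c] * 7.3
        net2 = tn.fit_clpn(scaled, scaled["id"], (1, 2), cfg)
        np.testing.assert_allclose(net2.W, net.W, atol=1e-10)

    def test_fewer_subjects_than_folds_propagates(self, var_panel):
        with pytest.raises(ValueError, match="n_folds"):
            tn.fit_clpn(var_panel, var_panel["id"][:8], (1, 2), LassoConfig(n_folds=10))

    def test_fixed_lambdas_skip_cv(self, var_panel):
        net = tn.fit_clpn(
            var_panel, var_panel["id"], (1, 2), LassoConfig(), lambdas=np.full(6, 0.05)
        )
        np.testing.assert_allclose(net.lambdas, 0.05)


class TestDisplayThreshold:
    def test_zero_threshold_identity(self, var_panel):
        net = tn.fit_clpn(var_panel, var_panel["id"], (1, 2), LassoConfig(fold_seed=1))
        disp = tn.apply_display_threshold(net, 0.0)
        np.testing.assert_array_equal(disp.W, net.W)

    def test_strict_inequality_and_source_untouched(self, var_panel):
        net = tn.fit_clpn(var_panel, var_panel["id"], (1, 2), LassoConfig(fold_seed=1))
        net.W[0, 1] = 0.049
        net.W[0, 2] = 0.050
        disp = tn.apply_display_threshold(net, 0.05)
        assert disp.W[0, 1] == 0.0 and disp.W[0, 2] == 0.050
        assert net.W[0, 1] == 0.049  # estimation copy unchanged

    def test_surviving_edge_count_matches_enumeration(self):
        # direct enumeration oracle on a fixed random matrix
        W = np.random.default_rng(1).uniform(-0.1, 0.1, size=(6, 6))
        from trajnet.clpn import CLPNetwork

        net = CLPNetwork(
            group="g", wave_pair=(1, 2), nodes=tn.NODES, W=W,
            covariate_coefs=np.zeros((3, 6)), lambdas=np.full(6, 0.01), n=100,
        )
        disp = tn.apply_display_threshold(net, 0.05)
        brute = sum(
            1 for i in range(6) for j in range(6) if abs(W[i, j]) >= 0.05
        )
        assert np.sum(disp.W != 0.0) == brute


def test_block_cv_matches_per_outcome_selection(var_panel):
    # the batched CV used inside fit_clpn must reproduce the one-outcome op
    from trajnet.clpn import _cv_lambdas_block

    b = standardize_block(var_panel, var_panel["id"], (1, 2))
    X = np.hstack([b.X_t, b.C])
    pf = (6, 7, 8)
    cfg = LassoConfig(fold_seed=9)
    block = _cv_lambdas_block(X, b.X_t1, cfg, pf)
    single = [cv_select_lambda(X, b.X_t1[:, j], cfg, pf) for j in range(6)]
    np.testing.assert_allclose(block, single)
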