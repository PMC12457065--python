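"""Growth-mixture fitting: likelihood correctness against a generic-optimizer
oracle, EM monotonicity, index formulas, enumeration logic and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import logsumexp

import trajnet as tn
from trajnet import gmm as G


def _direct_ml_loglik(Y, K, x0_model, maxiter=400):
    """Oracle: generic numerical maximization of the same closed-form marginal
    likelihood, parametrized unconstrained (softmax pi, log-Cholesky Sigma,
    log theta)."""
    n, T = Y.shape
    X = G._design(T)

    def unpack(v):
        i = 0
        logits = np.concatenate([[0.0], v[i : i + K - 1]]); i += K - 1
        pi = np.exp(logits - logsumexp(logits))
        mu = v[i : i + 2 * K].reshape(K, 2); i += 2 * K
        l11, l21, l22 = v[i : i + 3]; i += 3
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        Sigma = L @ L.T
        theta = np.exp(v[i : i + T])
        return pi, mu, Sigma, theta

    def nll(v):
        pi, mu, Sigma, theta = unpack(v)
        try:
            return -G._loglik(Y, pi, mu, Sigma, theta)
        except np.linalg.LinAlgError:
            return 1e10

    m = x0_model
    L0 = np.linalg.cholesky(m.Sigma + 1e-8 * np.eye(2))
    x0 = np.concatenate(
        [
            np.log(m.pi[1:] / m.pi[0]) if K > 1 else [],
            m.mu.ravel(),
            [np.log(L0[0, 0]), L0[1, 0], np.log(L0[1, 1])],
            np.log(np.maximum(m.theta, 1e-8)),
        ]
    )
    res = minimize(nll, x0, method="Nelder-Mead", options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-12})
    return -res.fun


class TestEMCore:
    def test_k1_em_matches_direct_maximization(self):
        panel = tn.generate_growth_panel(tn.default_growth_spec(n_subjects=150, seed=2))
        sub = panel[panel.true_class == 2]
        model = tn.fit_gmm(sub, 1, n_starts=2, seed=0)
        oracle = _direct_ml_loglik(G._as_y(sub), 1, model, maxiter=3000)
        assert model.loglik >= oracle - 1e-4
        assert abs(model.loglik - oracle) < 1e-3

    def test_k2_em_not_beaten_by_generic_optimizer(self, growth_panel, fitted_two_class):
        sub = growth_panel.iloc[:200]
        # ECM converges linearly; a tight tolerance is needed for a fair
        # head-to-head against simplex polishing of the same likelihood
        model = tn.fit_gmm(sub, 2, n_starts=4, seed=1, tol=1e-12, max_iter=20_000)
        oracle = _direct_ml_loglik(G._as_y(sub), 2, model, maxiter=2000)
        assert model.loglik >= oracle - 1e-4

    def test_loglik_trace_monotone(self, fitted_two_class):
        trace = fitted_two_class.loglik_trace
        assert np.all(np.diff(trace) >= -1e-6 * (1 + np.abs(trace[1:])))

    def test_separated_limit_recovers_exact_trajectories(self):
        spec = tn.default_growth_spec(
            n_subjects=200,
            seed=6,
            ranef_cov=((0.0, 0.0), (0.0, 0.0)),
            resid_vars=(1e-6, 1e-6, 1e-6),
        )
        panel = tn.generate_growth_panel(spec)
        model = tn.fit_gmm(panel, 2, n_starts=3, seed=0)
        # posteriors collapse to 0/1 and class means equal the class trajectories
        assert np.all(np.max(model.posteriors, axis=1) > 1 - 1e-9)
        np.testing.assert_allclose(model.mu[:, 0], [0.45, -0.14], atol=1e-3)
        np.testing.assert_allclose(model.mu[:, 1], [1.90, -0.59], atol=1e-3)

    def test_parameter_recovery_single_fit(self, fitted_two_class):
        m = fitted_two_class
        np.testing.assert_allclose(m.mu[0], [0.45, 1.90], atol=0.15)
        np.testing.assert_allclose(m.mu[1], [-0.14, -0.59], atol=0.10)
        assert abs(m.pi[0] - 0.2263) < 0.06

    def test_canonical_label_order(self, fitted_two_class):
        assert fitted_two_class.mu[0, 0] > fitted_two_class.mu[1, 0]

    def test_too_few_subjects_rejected(self, growth_panel):
        with pytest.raises(ValueError):
            tn.fit_gmm(growth_panel.iloc[:15], 2, n_starts=1, seed=0)


class TestFitIndices:
    def test_formula_identity_at_zero(self):
        m = G.GrowthMixtureModel(
            K=2, pi=np.array([0.5, 0.5]), mu=np.zeros((2, 2)),
            Sigma=np.eye(2), theta=np.ones(3), loglik=0.0, n_params=0,
            posteriors=np.tile([1.0, 0.0], (10, 1)), converged=True, n_starts_used=1,
        )
        idx = tn.fit_indices(m, n=100)
        assert idx.AIC == 0.0 and idx.aBIC == 0.0

    def test_hard_posteriors_give_entropy_one(self, rng):
        P = np.zeros((50, 3))
        P[np.arange(50), rng.integers(0, 3, 50)] = 1.0
        m = G.GrowthMixtureModel(
            K=3, pi=np.full(3, 1 / 3), mu=np.zeros((3, 2)), Sigma=np.eye(2),
            theta=np.ones(3), loglik=-1.0, n_params=14, posteriors=P,
            converged=True, n_starts_used=1,
        )
        assert tn.fit_indices(m, n=50).entropy == pytest.approx(1.0, abs=1e-12)

    def test_k1_entropy_absent(self, growth_panel):
        m = tn.fit_gmm(growth_panel.iloc[:100], 1, n_starts=1, seed=0)
        assert tn.fit_indices(m).entropy is None

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_entropy_bounds(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(3) * rng.uniform(0.2, 5.0), size=40)
        m = G.GrowthMixtureModel(
            K=3, pi=np.full(3, 1 / 3), mu=np.zeros((3, 2)), Sigma=np.eye(2),
            theta=np.ones(3), loglik=-1.0, n_params=14, posteriors=P,
            converged=True, n_starts_used=1,
        )
        e = tn.fit_indices(m, n=40).entropy
        assert -1e-12 <= e <= 1 + 1e-12

    def test_permutation_invariance(self, fitted_two_class):
        m = fitted_two_class
        idx = tn.fit_indices(m)
        import copy

        m2 = copy.deepcopy(m)
        m2.pi = m2.pi[::-1].copy()
        m2.mu = m2.mu[::-1].copy()
        m2.posteriors = m2.posteriors[:, ::-1].copy()
        idx2 = tn.fit_indices(m2)
        assert idx2.AIC == pytest.approx(idx.AIC)
        assert idx2.aBIC == pytest.approx(idx.aBIC)
        assert idx2.entropy == pytest.approx(idx.entropy, abs=1e-12)


class TestTests:
    def test_add_one_boundary(self):
        # observed statistic below every bootstrap draw -> p = 1
        assert G.add_one_pvalue(19, 19) == 1.0
        assert G.add_one_pvalue(0, 19) == pytest.approx(0.05)

    def test_lmr_no_improvement_gives_p_one(self):
        assert G.lmr_pvalue(-100.0, -100.0, n=500) == 1.0

    def test_lmr_power_on_separated_classes(self):
        ps = []
        for s in range(5):
            panel = tn.generate_growth_panel(
                tn.default_growth_spec(n_subjects=300, seed=60 + s)
            )
            ps.append(tn.lmr_lrt(panel, 2, n_starts=2, seed=s))
        assert all(p < 0.05 for p in ps)

    def test_lmr_type_one_error_bounded(self):
        # the chi-square reference is liberal; assert the documented bound
        # (rate <= 0.10) with binomial slack at 40 scaled replicates
        rejects = 0
        for r in range(40):
            spec = tn.GrowthSpec(
                n_subjects=200, class_props=(1.0,), class_intercepts=(0.0,),
                class_slopes=(-0.2,), seed=8000 + r,
            )
            panel = tn.generate_growth_panel(spec)
            rejects += tn.lmr_lrt(panel, 2, n_starts=2, seed=r) < 0.05
        assert rejects / 40 <= 0.10 + 2.5 * np.sqrt(0.10 * 0.90 / 40)

    def test_blrt_decisive_on_two_class_data(self, growth_panel):
        p = tn.blrt(growth_panel, 2, n_boot=19, n_starts=2, seed=0)
        assert p == pytest.approx(0.05)  # the add-one floor at 19 replicates


class TestSelection:
    def _fake(self, K, smallest_prop, blrt_p, converged=True):
        # likelihood gain of 30 per class comfortably beats the aBIC penalty
        n = 200
        m = G.GrowthMixtureModel(
            K=K, pi=np.full(K, 1 / K), mu=np.column_stack([np.linspace(1, 0, K), np.zeros(K)]),
            Sigma=np.eye(2), theta=np.ones(3), loglik=-500.0 + 30.0 * K, n_params=G.n_params(K),
            posteriors=np.tile(np.eye(K)[0], (n, 1)), converged=converged, n_starts_used=1,
        )
        idx = tn.fit_indices(m, n=n)
        idx.smallest_class_prop = smallest_prop
        idx.smallest_class_n = int(smallest_prop * n)
        idx.blrt_p = blrt_p
        return m, idx

    def test_small_class_violation_falls_back(self):
        fits = [
            self._fake(1, 1.0, None),
            self._fake(2, 0.2263, 0.001),
            self._fake(3, 0.0493, 0.001),
        ]
        assert tn.select_model(fits).recommended_K == 2

    def test_single_fit_recommends_one(self):
        assert tn.select_model([self._fake(1, 1.0, None)]).recommended_K == 1

    def test_nonsignificant_blrt_stops_growth(self):
        fits = [
            self._fake(1, 1.0, None),
            self._fake(2, 0.3, 0.001),
            self._fake(3, 0.15, 0.60),
        ]
        assert tn.select_model(fits).recommended_K == 2

    def test_empty_battery_rejected(self):
        with pytest.raises(ValueError):
            tn.select_model([])

    def test_nonconsecutive_rejected(self):
        with pytest.raises(ValueError):
            tn.select_model([self._fake(2, 0.3, 0.01)])


class TestClassify:
    def test_modal_and_max_posterior(self, fitted_two_class):
        a = tn.classify(fitted_two_class)
        np.testing.assert_array_equal(
            a.modal_class - 1, np.argmax(fitted_two_class.posteriors, axis=1)
        )
        assert np.all(a.max_posterior >= 0.5)

    def test_tie_breaks_to_lower_class(self):
        P = np.full((4, 2), 0.5)
        m = G.GrowthMixtureModel(
            K=2, pi=np.array([0.5, 0.5]), mu=np.array([[1.0, 0.0], [0.0, 0.0]]),
            Sigma=np.eye(2), theta=np.ones(3), loglik=-1.0, n_params=11,
            posteriors=P, converged=True, n_starts_used=1,
        )
        assert np.all(tn.classify(m).modal_class == 1)

    def test_recovered_split_near_truth(self, growth_panel, fitted_two_class):
        a = tn.classify(fitted_two_class)
        frac = np.mean(a.modal_class == 1)
        true_frac = (growth_panel["true_class"] == 1).mean()
        assert abs(frac - true_frac) < 0.03
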