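"""EBEN solver: initialization, s/q statistics, the alpha objective and
its maximizer, greedy updates, convergence, t-tests, and end-to-end fits
checked against an independent dense Bayesian oracle."""

import copy
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy import stats as sps

from eben.core import (
    Action,
    EBENHyperparams,
    SolverConfig,
    apply_update,
    check_convergence,
    compute_s_q,
    eben_fit,
    initialize_state,
    log_posterior_alpha,
    optimal_alpha,
    posterior_t_tests,
    select_update,
    update_noise_variance,
)
from eben.core import _optimal_alpha_vec, _recompute_stats


# ---------------------------------------------------------------------------
# independent dense oracles (computed through C, not through Sigma)
# ---------------------------------------------------------------------------


def oracle_posterior(XA, alphas, sigma0_sq, yc):
    """Posterior mean via the marginal covariance route.

    Prior beta ~ N(0, sigma0^2/alpha) gives C = sigma0^2 (I + X A^-1 X^T)
    and beta = (sigma0^2 A^-1) X^T C^-1 y~ — a different computational
    path from the solver's (X^T X + A)^-1 X^T y~.
    """
    prior_var = np.diag(sigma0_sq / np.asarray(alphas))
    C = sigma0_sq * np.eye(len(yc)) + XA @ prior_var @ XA.T
    return prior_var @ XA.T @ np.linalg.solve(C, yc)


def oracle_s_q(x, XA, alphas, sigma0_sq, yc):
    """Raw S/Q via the explicit inverse of C0 = I + X A^-1 X^T."""
    n = len(yc)
    C0 = np.eye(n)
    if XA.shape[1]:
        C0 = C0 + XA @ np.diag(1.0 / np.asarray(alphas)) @ XA.T
    Ci = np.linalg.inv(C0)
    return float(x @ Ci @ x), float(x @ Ci @ yc) / np.sqrt(sigma0_sq)


def numeric_alpha_max(s, q, lambda2):
    res = minimize_scalar(
        lambda t: -log_posterior_alpha(np.exp(t), s, q, lambda2),
        bounds=(np.log(1e-8), np.log(1e10)),
        method="bounded",
        options={"xatol": 1e-13},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


class TestInitialization:
    def test_mean_centering_and_noise_seed(self, rng):
        X = rng.standard_normal((4, 2))
        state = initialize_state(X, np.array([0.0, 1.0, 2.0, 3.0]))
        assert state.mu == pytest.approx(1.5)
        np.testing.assert_allclose(state.y_centered, [-1.5, -0.5, 0.5, 1.5])
        assert state.sigma0_sq == pytest.approx(0.1 * 5.0 / 4.0)

    def test_initial_candidate_is_largest_absolute_correlation(self):
        yc = np.array([1.0, -1.0, 1.0, -1.0])
        x1 = np.array([1.0, -1.0, 1.0, 0.0])  # x1^T y = 3
        x2 = np.array([-1.0, 1.0, -2.0, 1.0])  # x2^T y = -5
        state = initialize_state(np.column_stack([x1, x2]), yc)
        assert state.initial_candidate == 1

    def test_zero_mean_phenotype_untouched(self, rng):
        y = np.array([-1.0, 0.0, 1.0])
        state = initialize_state(rng.standard_normal((3, 2)), y)
        assert state.mu == 0.0
        np.testing.assert_array_equal(state.y_centered, y)

    def test_constant_phenotype_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            initialize_state(rng.standard_normal((5, 2)), np.ones(5))


# ---------------------------------------------------------------------------
# s/q statistics
# ---------------------------------------------------------------------------


class TestSQStatistics:
    def test_empty_model_identity_covariance(self):
        # sigma0^2 == 1 by construction: 0.1 * y~^T y~ / n = 1
        yc = np.array([1.0, 1.0, -1.0, -1.0]) * np.sqrt(10.0)
        x = np.array([2.0, 0.0, 0.0, 0.0])
        other = np.array([0.0, 1.0, 0.0, 0.0])
        state = initialize_state(np.column_stack([x, other]), yc)
        assert state.sigma0_sq == pytest.approx(1.0)
        s, q = compute_s_q(state, x)
        assert s == pytest.approx(4.0)
        assert q == pytest.approx(x @ yc)

    def test_matches_dense_oracle_with_active_features(self, rng):
        X = rng.standard_normal((12, 4))
        y = X[:, 0] + 0.2 * rng.standard_normal(12)
        state = initialize_state(X, y)
        apply_update(state, Action("add", 0, 2.5, 1.0))
        apply_update(state, Action("add", 2, 1.5, 1.0))
        XA = X[:, [0, 2]]
        for j in (1, 3):
            s, q = compute_s_q(state, X[:, j])
            s_o, q_o = oracle_s_q(
                X[:, j], XA, [2.5, 1.5], state.sigma0_sq, state.y_centered
            )
            assert s == pytest.approx(s_o, rel=1e-10)
            assert q == pytest.approx(q_o, rel=1e-10)

    def test_orthogonal_feature_unaffected_by_updates(self):
        # exactly orthogonal columns: adding one leaves the other's raw
        # statistics untouched (Woodbury correction vanishes)
        x1 = np.array([1.0, 1.0, 0.0, 0.0])
        x2 = np.array([0.0, 0.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, 2.0, 0.0])
        state = initialize_state(np.column_stack([x1, x2]), y)
        s_before, q_before = compute_s_q(state, x2)
        apply_update(state, Action("add", 0, 1.0, 1.0))
        s_after, q_after = compute_s_q(state, x2)
        assert s_after == pytest.approx(s_before, rel=1e-12)
        assert q_after == pytest.approx(q_before, rel=1e-12)


# ---------------------------------------------------------------------------
# the alpha objective and its maximizer
# ---------------------------------------------------------------------------


class TestAlphaObjective:
    def test_printed_form(self):
        assert log_posterior_alpha(1.0, 1.0, 3.0, 0.0) == pytest.approx(
            0.5 * (np.log(1.0 / 3.0) + 3.0), abs=1e-10
        )
        assert log_posterior_alpha(1.0, 1.0, 3.0, 0.5) == pytest.approx(
            0.5 * (np.log(1.0 / 3.0) + 3.0) - 0.5, abs=1e-10
        )

    def test_vanishes_at_infinite_alpha(self):
        assert log_posterior_alpha(1e14, 1.0, 3.0, 0.0) == pytest.approx(0.0, abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            log_posterior_alpha(0.0, 1.0, 3.0, 0.0)

    def test_closed_form_and_numeric_maximizer_agree(self):
        a = optimal_alpha(1.0, 3.0, EBENHyperparams())
        assert a == pytest.approx(4.0 / 7.0, abs=1e-6)
        assert a == pytest.approx(numeric_alpha_max(1.0, 3.0, 0.0), rel=1e-5)

    def test_gate_boundary_is_infinite(self):
        # q^2 - s == lambda1 + 2*lambda2 exactly: strict gate fails
        assert optimal_alpha(1.0, 2.0, EBENHyperparams(lambda1=3.0)) == np.inf
        assert optimal_alpha(1.0, 2.0, EBENHyperparams(lambda2=1.5)) == np.inf

    def test_zero_quality_never_enters(self):
        assert optimal_alpha(4.0, 0.0, EBENHyperparams()) == np.inf
        assert optimal_alpha(4.0, 0.0, EBENHyperparams(1.0, 1.0)) == np.inf

    def test_negative_sparsity_rejected(self):
        with pytest.raises(ValueError):
            optimal_alpha(-0.5, 1.0, EBENHyperparams())

    @pytest.mark.parametrize("lambda2", [0.001, 0.05, 0.7])
    def test_vectorized_path_matches_numeric_maximizer(self, rng, lambda2):
        s = rng.uniform(0.2, 20.0, size=40)
        z = rng.uniform(1.05, 9.0, size=40)
        q = np.sqrt((1.0 + s + 2.0 * lambda2) * z)
        out = _optimal_alpha_vec(s, q, 0.0, lambda2)
        for i in range(40):
            if np.isfinite(out[i]):
                ref = numeric_alpha_max(s[i], q[i], lambda2)
                assert out[i] == pytest.approx(ref, rel=1e-5)
                # stationarity of the alpha log-posterior
                eps = out[i] * 1e-6
                d = (
                    log_posterior_alpha(out[i] + eps, s[i], q[i], lambda2)
                    - log_posterior_alpha(out[i] - eps, s[i], q[i], lambda2)
                ) / (2 * eps)
                assert abs(d) < 1e-6


# ---------------------------------------------------------------------------
# greedy updates
# ---------------------------------------------------------------------------


class TestGreedyUpdates:
    def test_picks_largest_gain(self, small_regression):
        X, y = small_regression
        state = initialize_state(X, y)
        action = select_update(state, EBENHyperparams())
        assert action.kind == "add"
        assert action.gain > 0
        # the strong feature wins the first add
        assert action.feature == 2

    def test_noop_when_nothing_helps(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        state = initialize_state(X, y)
        # an absurdly large gate excludes everything
        action = select_update(state, EBENHyperparams(lambda1=1e9))
        assert action.kind == "noop"

    def test_add_then_delete_restores_state(self, small_regression):
        X, y = small_regression
        state = initialize_state(X, y)
        apply_update(state, Action("add", 2, 3.0, 1.0))
        before = copy.deepcopy(state)
        apply_update(state, Action("add", 4, 5.0, 1.0))
        apply_update(state, Action("delete", 4))
        np.testing.assert_allclose(state.beta, before.beta, atol=1e-8)
        np.testing.assert_allclose(
            state.posterior_cov, before.posterior_cov, atol=1e-8
        )
        np.testing.assert_allclose(state.S_raw, before.S_raw, atol=1e-8)
        np.testing.assert_allclose(state.Q_raw, before.Q_raw, atol=1e-8)
        assert state.active == before.active

    def test_noop_leaves_state_unchanged(self, small_regression):
        X, y = small_regression
        state = initialize_state(X, y)
        before = copy.deepcopy(state)
        apply_update(state, Action("noop"))
        np.testing.assert_array_equal(state.S_raw, before.S_raw)
        assert state.active == before.active

    def test_incremental_stats_match_scratch_recompute(self, rng):
        X = rng.standard_normal((50, 8))
        y = X[:, 1] - 0.8 * X[:, 5] + 0.3 * rng.standard_normal(50)
        state = initialize_state(X, y)
        hp = EBENHyperparams(0.01, 0.01)
        for _ in range(12):
            action = select_update(state, hp)
            if action.kind == "noop":
                break
            apply_update(state, action)
            S_inc, Q_inc = state.S_raw.copy(), state.Q_raw.copy()
            _recompute_stats(state)
            np.testing.assert_allclose(S_inc, state.S_raw, atol=1e-8)
            np.testing.assert_allclose(Q_inc, state.Q_raw, atol=1e-8)

    def test_posterior_matches_dense_oracle_after_add(self, rng):
        X = rng.standard_normal((10, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(10)
        state = initialize_state(X, y)
        apply_update(state, Action("add", 0, 2.0, 1.0))
        expected = oracle_posterior(
            X[:, [0]], [2.0], state.sigma0_sq, state.y_centered
        )
        np.testing.assert_allclose(state.beta, expected, atol=1e-10)


class TestNoiseVariance:
    def test_empty_active_set_unchanged(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        state = initialize_state(X, y)
        before = state.sigma0_sq
        update_noise_variance(state)
        assert state.sigma0_sq == before

    def test_perfect_fit_hits_floor(self):
        x = np.array([1.0, 2.0, -1.0, 0.5, -2.5])
        y = x - x.mean() * 0  # y exactly proportional to the column
        state = initialize_state(x[:, None], y)
        apply_update(state, Action("add", 0, 1e-9, 1.0))
        for _ in range(60):
            update_noise_variance(state)
        assert state.sigma0_sq < 1e-6

    def test_recovers_planted_noise_level(self):
        rng = np.random.default_rng(7)
        n, sigma = 500, 1.0
        X = rng.standard_normal((n, 10))
        y = X[:, 0] - 1.2 * X[:, 4] + 0.9 * X[:, 7] + rng.normal(0, sigma, n)
        fit = eben_fit(X, y, EBENHyperparams(0.01, 0.01))
        assert fit.sigma0_sq == pytest.approx(sigma**2, rel=0.2)


class TestConvergence:
    CFG = SolverConfig()

    def test_identical_maps_converged(self):
        a = {1: 2.0, 5: 3.0}
        assert check_convergence(a, dict(a), True, self.CFG)

    def test_large_change_not_converged(self):
        assert not check_convergence(
            {1: 1.0}, {1: 1.0 + 2e-6}, True, self.CFG
        )

    def test_no_candidate_converges_regardless(self):
        assert check_convergence({1: 1.0}, {1: 99.0}, False, self.CFG)

    def test_membership_change_not_converged(self):
        assert not check_convergence({1: 1.0}, {1: 1.0, 2: 5.0}, True, self.CFG)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


class TestPosteriorTTests:
    def test_df_and_p_consistency(self, rng):
        n = 100
        X = rng.standard_normal((n, 8))
        y = X[:, 0] + 0.5 * rng.standard_normal(n)
        state = initialize_state(X, y)
        for j, a in zip(range(5), (2.0, 3.0, 4.0, 5.0, 6.0)):
            apply_update(state, Action("add", j, a, 1.0))
        fit = posterior_t_tests(state, SolverConfig())
        df = n - 5 - 1
        assert df == 94
        for row in fit.rows:
            assert row.t == pytest.approx(row.beta / row.se, rel=1e-12)
            assert row.p == pytest.approx(2 * sps.t.sf(abs(row.t), df), rel=1e-12)

    def test_doubling_se_shrinks_t(self):
        # monotonicity: |t| halves and p grows when se doubles
        t1, t2 = 2.0 / 1.0, 2.0 / 2.0
        p1 = 2 * sps.t.sf(t1, 50)
        p2 = 2 * sps.t.sf(t2, 50)
        assert t2 == t1 / 2 and p2 > p1

    def test_oversaturated_model_is_error(self, rng):
        X = np.linalg.qr(rng.standard_normal((5, 4)))[0]
        y = rng.standard_normal(5)
        state = initialize_state(X, y)
        for j in range(4):
            apply_update(state, Action("add", j, 1.0, 1.0))
        with pytest.raises(ValueError, match="saturated"):
            posterior_t_tests(state, SolverConfig())


# ---------------------------------------------------------------------------
# end-to-end fits
# ---------------------------------------------------------------------------


class TestEbenFit:
    def test_perfect_univariate_fit(self):
        # zero-mean column, so y = x is exactly mu + 1*x with mu = 0
        x = np.array([0.5, -1.0, 2.0, 1.5, -0.7, -2.3])
        fit = eben_fit(x[:, None], x.copy())
        assert [r.index for r in fit.rows] == [0]
        assert fit.rows[0].beta == pytest.approx(1.0, rel=1e-3)
        assert fit.sigma0_sq < 1e-6

    def test_single_effect_recovered_within_ten_percent(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200, 20))
        y = 2.0 * X[:, 3] + 0.3 * rng.standard_normal(200)
        fit = eben_fit(X, y, EBENHyperparams(0.1, 0.1))
        sig = {r.index: r.beta for r in fit.significant}
        assert 3 in sig
        assert sig[3] == pytest.approx(2.0, rel=0.1)

    def test_null_data_selects_almost_nothing(self):
        counts = []
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((100, 20))
            y = rng.standard_normal(100)
            fit = eben_fit(X, y, EBENHyperparams(1.0, 1.0))
            counts.append(len(fit.rows))
        assert np.mean(counts) <= 1.0

    def test_deterministic(self, small_regression):
        X, y = small_regression
        f1 = eben_fit(X, y, EBENHyperparams(0.01, 0.01))
        f2 = eben_fit(X, y, EBENHyperparams(0.01, 0.01))
        assert [(r.index, r.beta) for r in f1.rows] == [
            (r.index, r.beta) for r in f2.rows
        ]

    def test_monotone_ascent(self, small_regression):
        X, y = small_regression
        fit = eben_fit(X, y, EBENHyperparams(0.01, 0.01))
        assert fit.history, "expected at least one greedy action"
        assert all(gain > 0 for _, _, gain in fit.history)

    def test_scaling_consistency(self):
        # scaling y by c scales fitted betas by c (lambda1 = lambda2 = 0);
        # the objective's +1 term makes this exact only as s -> infinity,
        # hence the modest tolerance
        rng = np.random.default_rng(21)
        X = rng.standard_normal((150, 6))
        y = 1.2 * X[:, 1] - 0.9 * X[:, 4] + 0.2 * rng.standard_normal(150)
        f1 = eben_fit(X, y, EBENHyperparams())
        f2 = eben_fit(X, 10.0 * y, EBENHyperparams())
        b1 = {r.index: r.beta for r in f1.significant}
        b2 = {r.index: r.beta for r in f2.significant}
        assert set(b1) == set(b2)
        for j in b1:
            assert b2[j] == pytest.approx(10.0 * b1[j], rel=1e-3)

    def test_orthogonal_null_feature_never_selected(self):
        # q = 0 for a column orthogonal to the response: the gate can
        # never hold, so it never appears in the model
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        signal = y.copy()
        null = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])  # orthogonal to y
        fit = eben_fit(np.column_stack([signal, null]), y + 0.0)
        assert all(r.index != 1 for r in fit.rows)

    def test_max_iterations_warns(self, small_regression):
        X, y = small_regression
        with pytest.warns(RuntimeWarning, match="max_iterations"):
            eben_fit(X, y, EBENHyperparams(), SolverConfig(max_iterations=1))

    def test_dense_oracle_equivalence_small_instances(self):
        """Converged (beta, alpha) match the dense posterior computed
        through C, and every applied action strictly increased L."""
        rng = np.random.default_rng(99)
        checked = 0
        for trial in range(20):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(2, 5))
            X = rng.standard_normal((n, k))
            beta_true = np.zeros(k)
            beta_true[rng.integers(0, k)] = rng.uniform(1.0, 2.0)
            y = X @ beta_true + 0.4 * rng.standard_normal(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = eben_fit(X, y, EBENHyperparams(0.05, 0.05))
            assert all(g > 0 for _, _, g in fit.history)
            if not fit.rows:
                continue
            checked += 1
            idx = fit.active_indices
            scales = np.array([fit.column_scales[j] for j in idx])
            Xs = X[:, idx] / scales
            alphas = [fit.alpha[j] for j in idx]
            expected = oracle_posterior(
                Xs, alphas, fit.sigma0_sq, y - y.mean()
            ) / scales
            np.testing.assert_allclose(fit.betas, expected, atol=1e-8)
        assert checked >= 5
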