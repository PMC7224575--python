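import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sparselmm.kinship import RotatedData
from sparselmm.likelihood import PenaltySpec, ThetaState, dtilde_diag, objective
from sparselmm.solver import (fit_lambda, kkt_residuals, soft_threshold,
                              update_beta, update_eta, update_sigma2)

from conftest import random_rotated_problem


def naive_weighted_lasso(Xt, y, w, lamv, n_iter=20000, tol=1e-12):
    """Independent brute-force coordinate-descent oracle (plain python).

    Minimizes 0.5 * sum_i w_i (y_i - Xt_i beta)^2 + sum_j lamv_j |beta_j|.
    """
    p1 = Xt.shape[1]
    beta = np.zeros(p1)
    for _ in range(n_iter):
        change = 0.0
        for j in range(p1):
            r = y - Xt @ beta + Xt[:, j] * beta[j]
            num = np.sum(w * Xt[:, j] * r)
            den = np.sum(w * Xt[:, j] ** 2)
            if den == 0:
                new = 0.0
            else:
                t = lamv[j]
                new = np.sign(num) * max(abs(num) - t, 0.0) / den
            change = max(change, abs(new - beta[j]))
            beta[j] = new
        if change < tol:
            break
    return beta


class TestSoftThreshold:
    @pytest.mark.parametrize("x,t,expected", [(2.0, 1.5, 0.5),
                                              (-2.0, 1.5, -0.5),
                                              (2.0, 3.0, 0.0),
                                              (0.0, 0.0, 0.0)])
    def test_known_values(self, x, t, expected):
        assert soft_threshold(x, t) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_toward_zero_and_contracts(self, x, t):
        s = soft_threshold(x, t)
        assert abs(s) <= abs(x) + 1e-12
        assert s * x >= 0.0
        assert abs(s - x) <= t + 1e-12

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestUpdateBeta:
    def test_orthonormal_design_least_squares(self, rng):
        # lambda = 0, identity weights, orthonormal columns: one sweep gives
        # exactly beta = Xtilde' Ytilde
        n = 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        rot = RotatedData(Ytilde=rng.standard_normal(n), Xtilde=Q,
                          Lambda=np.ones(n))
        theta = ThetaState(beta=np.zeros(4), eta=0.0, sigma2=1.0)
        pen = PenaltySpec(lam=0.0, p=3)
        beta = update_beta(theta, rot, pen)
        np.testing.assert_allclose(beta, Q.T @ rot.Ytilde, atol=1e-10)

    def test_degenerate_column_stays_zero(self, rng):
        n = 6
        X = np.column_stack([np.ones(n), np.zeros(n), rng.standard_normal(n)])
        rot = RotatedData(Ytilde=rng.standard_normal(n), Xtilde=X,
                          Lambda=np.ones(n))
        theta = ThetaState(beta=np.zeros(3), eta=0.0, sigma2=1.0)
        beta = update_beta(theta, rot, PenaltySpec(lam=0.1, p=2))
        assert beta[1] == 0.0

    def test_sweep_never_increases_objective(self, rng):
        prob = random_rotated_problem(10, 4, rng)
        pen = PenaltySpec(lam=0.5, p=4)
        theta = ThetaState(beta=rng.standard_normal(5), eta=0.3, sigma2=1.1)
        before = objective(theta, prob["rot"], pen)
        theta2 = ThetaState(beta=update_beta(theta, prob["rot"], pen),
                            eta=0.3, sigma2=1.1)
        assert objective(theta2, prob["rot"], pen) <= before + 1e-10


class TestUpdateEta:
    def test_flat_objective_tie_breaks_low(self):
        rot = RotatedData(Ytilde=np.array([1.0, -1.0]),
                          Xtilde=np.ones((2, 1)), Lambda=np.ones(2))
        theta = ThetaState(beta=np.zeros(1), eta=0.5, sigma2=1.0)
        assert update_eta(theta, rot) == pytest.approx(0.01)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_fine_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        prob = random_rotated_problem(12, 3, rng)
        theta = ThetaState(beta=rng.standard_normal(4), eta=0.5, sigma2=1.3)
        got = update_eta(theta, prob["rot"])
        rot = prob["rot"]
        r2 = (rot.Ytilde - rot.Xtilde @ theta.beta) ** 2
        grid = np.arange(0.01, 0.99 + 1e-12, 1e-4)
        d = 1.0 + np.outer(grid, rot.Lambda - 1.0)
        vals = 0.5 * np.log(d).sum(axis=1) + (0.5 / theta.sigma2) * (1 / d) @ r2
        best = grid[np.argmin(vals)]
        assert abs(got - best) < 1e-3

    def test_zero_residuals_minimize_logdet_alone(self, rng):
        # residuals identically zero: only the log-determinant matters
        Lam = np.array([3.0, 1.2, 0.3, 0.1])
        X = np.column_stack([np.ones(4)])
        rot = RotatedData(Ytilde=X[:, 0] * 2.0, Xtilde=X, Lambda=Lam)
        theta = ThetaState(beta=np.array([2.0]), eta=0.5, sigma2=1.0)
        got = update_eta(theta, rot)
        grid = np.arange(0.01, 0.99 + 1e-12, 1e-4)
        vals = 0.5 * np.log(1 + np.outer(grid, Lam - 1)).sum(axis=1)
        assert abs(got - grid[np.argmin(vals)]) < 1e-3


class TestUpdateSigma2:
    def test_zero_residuals_floored(self):
        rot = RotatedData(Ytilde=np.ones(3), Xtilde=np.ones((3, 1)),
                          Lambda=np.ones(3))
        theta = ThetaState(beta=np.array([1.0]), eta=0.0, sigma2=1.0)
        with pytest.warns(RuntimeWarning):
            assert update_sigma2(theta, rot) == pytest.approx(1e-12)

    def test_unit_dtilde_gives_mean_square_residual(self, rng):
        prob = random_rotated_problem(9, 2, rng)
        theta = ThetaState(beta=np.zeros(3), eta=0.0, sigma2=1.0)
        rot = prob["rot"]
        expected = np.mean((rot.Ytilde - rot.Xtilde @ theta.beta) ** 2)
        assert update_sigma2(theta, rot) == pytest.approx(expected)

    def test_matches_grid_argmin_of_profile(self, rng):
        prob = random_rotated_problem(10, 2, rng)
        theta = ThetaState(beta=rng.standard_normal(3), eta=0.4, sigma2=1.0)
        got = update_sigma2(theta, prob["rot"])
        rot = prob["rot"]
        d = dtilde_diag(0.4, rot.Lambda)
        r2 = (rot.Ytilde - rot.Xtilde @ theta.beta) ** 2
        grid = np.arange(1e-4, 5.0, 1e-4)
        vals = 0.5 * rot.n * np.log(grid) + np.sum(r2 / d) / (2 * grid)
        assert abs(got - grid[np.argmin(vals)]) < 2e-4


class TestFitLambda:
    def test_fixed_point_returns_immediately(self, rng):
        prob = random_rotated_problem(10, 3, rng)
        pen = PenaltySpec(lam=2.0, p=3)
        init = ThetaState(np.zeros(4), 0.2, 1.0)
        theta, _ = fit_lambda(prob["rot"], pen, init, tol=1e-8, max_iter=500)
        theta2, diag2 = fit_lambda(prob["rot"], pen, theta, tol=1e-6)
        assert diag2.n_iter <= 2
        np.testing.assert_allclose(theta2.beta, theta.beta, atol=1e-6)

    def test_identity_kinship_matches_bruteforce_lasso(self, rng):
        # p = 2, N = 5, eta frozen at 0: the fit is a plain lasso and must
        # match the independent naive coordinate-descent oracle
        n, p = 5, 2
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        y = rng.standard_normal(n)
        rot = RotatedData(Ytilde=y, Xtilde=X, Lambda=np.ones(n))
        pen = PenaltySpec(lam=0.7, p=p)
        init = ThetaState(np.zeros(p + 1), 0.0, 1.0)
        theta, d = fit_lambda(rot, pen, init, tol=1e-10, max_iter=5000,
                              update_variance=False)
        oracle = naive_weighted_lasso(X, y, np.ones(n),
                                      0.7 * np.array([0.0, 1.0, 1.0]))
        np.testing.assert_allclose(theta.beta, oracle, atol=1e-5)

    def test_objective_trace_descent_invariant(self, rng):
        # adaptive-variance fits: every cycle descends up to the provable
        # penalty-rescaling allowance (see FitDiagnostics)
        prob = random_rotated_problem(20, 6, rng)
        pen = PenaltySpec(lam=1.0, p=6)
        init = ThetaState(np.zeros(7), 0.2, float(np.var(prob["Y"])))
        _, diag = fit_lambda(prob["rot"], pen, init, tol=1e-8, max_iter=300)
        assert np.all(diag.descent_violations() <= 1e-10)

    def test_objective_trace_strictly_monotone_frozen_variance(self, rng):
        prob = random_rotated_problem(20, 6, rng)
        pen = PenaltySpec(lam=1.0, p=6)
        init = ThetaState(np.zeros(7), 0.0, 1.0)
        _, diag = fit_lambda(prob["rot"], pen, init, tol=1e-8, max_iter=300,
                             update_variance=False)
        assert np.all(np.diff(diag.objective_trace) <= 1e-10)

    def test_objective_trace_strictly_monotone_unpenalized(self, rng):
        # lam = 0: the objective is the likelihood itself; every block is an
        # exact likelihood descent step, so the trace is monotone
        prob = random_rotated_problem(20, 4, rng)
        pen = PenaltySpec(lam=0.0, p=4)
        init = ThetaState(np.zeros(5), 0.2, float(np.var(prob["Y"])))
        _, diag = fit_lambda(prob["rot"], pen, init, tol=1e-8, max_iter=300)
        assert np.all(np.diff(diag.objective_trace) <= 1e-10)

    def test_kkt_residuals_small_at_convergence(self, rng):
        prob = random_rotated_problem(25, 8, rng)
        pen = PenaltySpec(lam=0.8, p=8)
        init = ThetaState(np.zeros(9), 0.2, float(np.var(prob["Y"])))
        theta, diag = fit_lambda(prob["rot"], pen, init, tol=1e-9,
                                 max_iter=2000)
        assert diag.converged
        assert np.max(kkt_residuals(theta, prob["rot"], pen)) < 1e-4

    def test_solution_invariant_to_coordinate_order(self, rng):
        prob = random_rotated_problem(15, 5, rng)
        pen = PenaltySpec(lam=0.5, p=5)
        init = ThetaState(np.zeros(6), 0.2, 1.0)
        theta, _ = fit_lambda(prob["rot"], pen, init, tol=1e-10, max_iter=2000)
        rot = prob["rot"]
        perm = np.array([0, 3, 1, 5, 2, 4])  # keep intercept first
        rot2 = RotatedData(Ytilde=rot.Ytilde, Xtilde=rot.Xtilde[:, perm],
                           Lambda=rot.Lambda)
        theta2, _ = fit_lambda(rot2, pen, init, tol=1e-10, max_iter=2000)
        np.testing.assert_allclose(theta2.beta[np.argsort(perm)], theta.beta,
                                   atol=1e-5)

    def test_max_iter_reached_flags_nonconvergence(self, rng):
        prob = random_rotated_problem(15, 5, rng)
        pen = PenaltySpec(lam=0.01, p=5)
        init = ThetaState(np.zeros(6), 0.5, 10.0)
        theta, diag = fit_lambda(prob["rot"], pen, init, tol=1e-14, max_iter=2)
        assert not diag.converged
        assert diag.n_iter == 2
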