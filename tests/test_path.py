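import numpy as np
import pytest

from sparselmm.kinship import RotatedData
from sparselmm.likelihood import PenaltySpec, ThetaState, nll
from sparselmm.path import (PathResult, fit_null_kkt, fit_path, gic,
                            lambda_max, lambda_sequence, profile_variance,
                            select_gic)
from sparselmm.solver import fit_lambda

from conftest import random_rotated_problem


class TestFitNullKkt:
    def test_identity_kinship_closed_forms(self, rng):
        # Phi = I: dtilde is 1 for every eta, so beta0 is the weighted mean
        # and sigma2 the mean squared centered response; eta hits the lower
        # bound by the flat-profile tie-break
        n = 40
        y = rng.standard_normal(n) + 2.0
        rot = RotatedData(Ytilde=y, Xtilde=np.ones((n, 1)), Lambda=np.ones(n))
        theta = fit_null_kkt(rot)
        assert theta.beta[0] == pytest.approx(y.mean(), abs=1e-8)
        assert theta.sigma2 == pytest.approx(np.mean((y - y.mean()) ** 2),
                                             abs=1e-8)
        assert theta.eta == pytest.approx(0.01)

    def test_kkt_equations_mutually_consistent(self, rng):
        prob = random_rotated_problem(30, 4, rng)
        theta = fit_null_kkt(prob["rot"])
        rot = prob["rot"]
        d = 1 + theta.eta * (rot.Lambda - 1)
        x0 = rot.Xtilde[:, 0]
        r = rot.Ytilde - x0 * theta.beta[0]
        # stationarity of beta0 and sigma2 at the solved eta
        assert np.sum(x0 * r / d) == pytest.approx(0.0, abs=1e-6)
        assert theta.sigma2 == pytest.approx(np.mean(r ** 2 / d), rel=1e-6)
        assert np.all(theta.beta[1:] == 0)

    def test_constant_response(self):
        n = 10
        rot = RotatedData(Ytilde=np.full(n, 3.0), Xtilde=np.ones((n, 1)),
                          Lambda=np.ones(n))
        theta = fit_null_kkt(rot)
        assert theta.beta[0] == pytest.approx(3.0)
        assert theta.sigma2 <= 1e-10


class TestLambdaMax:
    def test_orthogonal_columns_give_zero(self, rng):
        n = 10
        y = np.ones(n)
        X = np.column_stack([np.ones(n), np.zeros((n, 2))])
        rot = RotatedData(Ytilde=y, Xtilde=X, Lambda=np.ones(n))
        theta0 = fit_null_kkt(rot)
        assert lambda_max(rot, theta0, np.array([0.0, 1.0, 1.0])) == 0.0

    def test_doubling_penalty_factors_halves(self, rng):
        prob = random_rotated_problem(20, 5, rng)
        theta0 = fit_null_kkt(prob["rot"])
        v = np.r_[0.0, np.ones(5)]
        l1 = lambda_max(prob["rot"], theta0, v)
        l2 = lambda_max(prob["rot"], theta0, 2 * v)
        assert l2 == pytest.approx(l1 / 2)

    def test_all_zero_factors_error(self, rng):
        prob = random_rotated_problem(10, 2, rng)
        theta0 = fit_null_kkt(prob["rot"])
        with pytest.raises(ValueError):
            lambda_max(prob["rot"], theta0, np.zeros(3))

    @pytest.mark.parametrize("seed", range(20))
    def test_boundary_property(self, seed):
        """All penalized coefficients vanish at 1.001*lambda_max and at least
        one is nonzero at 0.9*lambda_max."""
        rng = np.random.default_rng(seed)
        prob = random_rotated_problem(25, 6, rng)
        rot = prob["rot"]
        theta0 = fit_null_kkt(rot)
        v = np.r_[0.0, np.ones(6)]
        lmax = lambda_max(rot, theta0, v)
        hi, _ = fit_lambda(rot, PenaltySpec(lam=1.001 * lmax, p=6), theta0,
                           tol=1e-9, max_iter=500)
        assert np.all(hi.beta[1:] == 0.0)
        lo, _ = fit_lambda(rot, PenaltySpec(lam=0.9 * lmax, p=6), theta0,
                           tol=1e-9, max_iter=500)
        assert np.count_nonzero(lo.beta[1:]) >= 1


class TestLambdaSequence:
    def test_log_spacing(self):
        np.testing.assert_allclose(lambda_sequence(1.0, 3, 0.01),
                                   [1.0, 0.1, 0.01], atol=1e-12)

    def test_endpoints_exact_and_ratios_constant(self):
        seq = lambda_sequence(7.3, 25, 0.001)
        assert seq[0] == pytest.approx(7.3)
        assert seq[-1] == pytest.approx(7.3e-3)
        ratios = seq[1:] / seq[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            lambda_sequence(0.0, 10, 0.01)


class TestGic:
    def test_hdbic_arithmetic(self):
        expected = 20 + np.log(np.log(100)) * np.log(50) * 3
        assert gic(10.0, 3, 100, 50) == pytest.approx(expected)

    def test_zero_an_gives_twice_nll(self):
        assert gic(7.0, 5, 100, 50, a_n=0.0) == pytest.approx(14.0)

    def test_bic_uses_log_n(self):
        assert gic(1.0, 4, 100, 50, a_n="bic") == pytest.approx(
            2.0 + np.log(100) * 4)

    def test_monotone_in_df(self):
        assert gic(5.0, 10, 200, 50) > gic(5.0, 3, 200, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            gic(1.0, 3, 2, 10)


class TestFitPathAndSelect:
    def test_path_invariants_and_empty_first_support(self, rng):
        prob = random_rotated_problem(40, 10, rng)
        path = fit_path(prob["rot"], K=12)
        assert np.all(np.diff(path.lambdas) < 0)
        assert path.df[0] == 2  # empty support at lambda_max
        assert np.all(np.isfinite(path.gic[path.converged]))
        for i, theta in enumerate(path.thetas):
            assert path.df[i] == np.count_nonzero(theta.beta[1:]) + 2

    def test_warm_and_cold_starts_agree(self, rng):
        prob = random_rotated_problem(35, 6, rng, eta=0.2)
        path = fit_path(prob["rot"], K=8, tol=1e-8)
        theta0 = fit_null_kkt(prob["rot"])
        for i in [2, 5, 7]:
            pen = PenaltySpec(lam=path.lambdas[i], p=6)
            cold, _ = fit_lambda(prob["rot"], pen, theta0, tol=1e-8,
                                 max_iter=3000)
            warm_support = np.flatnonzero(path.thetas[i].beta[1:])
            cold_support = np.flatnonzero(cold.beta[1:])
            np.testing.assert_array_equal(warm_support, cold_support)

    def test_pure_noise_keeps_supports_sparse(self, rng):
        n = 60
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 20))])
        rot = RotatedData(Ytilde=y, Xtilde=X, Lambda=np.ones(n))
        path = fit_path(rot, K=20)
        i = select_gic(path)
        assert path.df[i] - 2 <= 2

    def test_select_gic_tie_prefers_larger_lambda(self):
        theta = ThetaState(np.zeros(2), 0.5, 1.0)
        from sparselmm.solver import FitDiagnostics
        diag = FitDiagnostics(1, True, np.zeros(1), 0.0)
        path = PathResult(lambdas=np.array([2.0, 1.0]),
                          thetas=[theta, theta], df=np.array([2, 2]),
                          nll=np.array([5.0, 5.0]), gic=np.array([3.0, 3.0]),
                          diagnostics=[diag, diag], n=50, p=10)
        assert select_gic(path) == 0

    def test_select_gic_requires_converged_fit(self):
        theta = ThetaState(np.zeros(2), 0.5, 1.0)
        from sparselmm.solver import FitDiagnostics
        diag = FitDiagnostics(1, False, np.zeros(1), 1.0)
        path = PathResult(lambdas=np.array([1.0]), thetas=[theta],
                          df=np.array([2]), nll=np.array([1.0]),
                          gic=np.array([1.0]), diagnostics=[diag], n=50, p=10)
        with pytest.raises(ValueError):
            select_gic(path)

    def test_profile_variance_matches_reported_nll(self, rng):
        prob = random_rotated_problem(30, 5, rng)
        path = fit_path(prob["rot"], K=6)
        for i in [1, 4]:
            theta = path.thetas[i]
            e, s = profile_variance(theta.beta, prob["rot"])
            assert theta.eta == pytest.approx(e)
            assert theta.sigma2 == pytest.approx(s)
            assert path.nll[i] == pytest.approx(nll(theta, prob["rot"]))
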