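"""KKT-derived lambda sequence, warm-started path fitting and GIC selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .kinship import RotatedData
from .likelihood import (ETA_MAX, ETA_MIN, SIGMA2_FLOOR, PenaltySpec,
                         ThetaState, dtilde_diag, nll)
from .solver import fit_lambda

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PathResult:
    """Per-lambda fits with degrees of freedom, likelihoods and GIC values."""

    lambdas: np.ndarray
    thetas: list
    df: np.ndarray
    nll: np.ndarray
    gic: np.ndarray
    diagnostics: list
    n: int
    p: int

    @property
    def converged(self) -> np.ndarray:
        return np.array([d.converged for d in self.diagnostics], dtype=bool)

    def supports(self) -> list:
        """Nonzero penalized-coefficient index sets, one per lambda."""
        return [np.flatnonzero(t.beta[1:]) for t in self.thetas]


def fit_null_kkt(data: RotatedData) -> ThetaState:
    """Solve the null (all penalized beta = 0) KKT system.

    At the null, beta0 and sigma2 have closed forms given eta, so eta is found
    by minimizing the profiled negative log-likelihood on [0.01, 0.99]
    (coarse grid + bounded refinement), and the closed forms are re-applied at
    the solution so the three stationarity equations are mutually consistent.
    """
    x0 = data.Xtilde[:, 0]
    y = data.Ytilde
    Lam = data.Lambda
    n = data.n

    def closed_forms(eta):
        d = dtilde_diag(eta, Lam)
        b0 = float(np.sum(x0 * y / d) / np.sum(x0 * x0 / d))
        r = y - x0 * b0
        s2 = max(float(np.mean(r * r / d)), SIGMA2_FLOOR)
        return b0, s2, d, r

    def profile_nll(eta):
        b0, s2, d, r = closed_forms(eta)
        return (0.5 * n * (_LOG_2PI + np.log(s2)) + 0.5 * np.sum(np.log(d))
                + 0.5 / s2 * np.sum(r * r / d))

    grid = np.linspace(ETA_MIN, ETA_MAX, 64)
    vals = np.array([profile_nll(e) for e in grid])
    k = int(np.argmin(vals))
    res = minimize_scalar(profile_nll, bounds=(grid[max(k - 1, 0)],
                                               grid[min(k + 1, len(grid) - 1)]),
                          method="bounded", options={"xatol": 1e-10})
    eta = float(res.x)
    if profile_nll(ETA_MIN) <= res.fun + 1e-12:
        eta = ETA_MIN  # flat profile: prefer the simpler iid model
    b0, s2, _, _ = closed_forms(eta)
    beta = np.zeros(data.p + 1)
    beta[0] = b0
    return ThetaState(beta=beta, eta=eta, sigma2=s2)


def profile_variance(beta: np.ndarray, data: RotatedData):
    """Exact ML (eta, sigma2) given fixed beta.

    sigma2 has the closed form (1/N) sum r_i^2/dtilde_i at any eta, so eta is
    found by minimizing the profiled negative log-likelihood on [0.01, 0.99]
    (global grid + bounded refinement; at fixed beta the residuals are fixed
    and the profile has no degenerate direction).
    """
    r = data.Ytilde - data.Xtilde @ beta
    r2 = r * r
    Lam = data.Lambda
    n = data.n

    def profile_nll(eta):
        d = dtilde_diag(eta, Lam)
        s2 = max(float(np.mean(r2 / d)), SIGMA2_FLOOR)
        return 0.5 * n * np.log(s2) + 0.5 * np.sum(np.log(d))

    grid = np.linspace(ETA_MIN, ETA_MAX, 64)
    vals = np.array([profile_nll(e) for e in grid])
    k = int(np.argmin(vals))
    res = minimize_scalar(profile_nll,
                          bounds=(grid[max(k - 1, 0)],
                                  grid[min(k + 1, len(grid) - 1)]),
                          method="bounded", options={"xatol": 1e-10})
    eta = float(res.x)
    if profile_nll(ETA_MIN) <= res.fun + 1e-12:
        eta = ETA_MIN
    s2 = max(float(np.mean(r2 / dtilde_diag(eta, Lam))), SIGMA2_FLOOR)
    return eta, s2


def lambda_max(data: RotatedData, theta0: ThetaState,
               pen_factors: np.ndarray) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    lambda_max = max_j |(1/v_j) sum_i w_i Xtilde_ij (Ytilde_i - Xtilde_i0 b0)|
    over penalized columns with v_j > 0, with relatedness weights
    w_i = 1/dtilde_i at the null fit's eta (sigma2 cancels against the
    scale-equivariant penalty, so it does not appear).
    """
    v = np.asarray(pen_factors, dtype=float)
    pen = v[1:]
    if not np.any(pen > 0):
        raise ValueError("lambda_max undefined: all penalty factors are 0")
    w = 1.0 / dtilde_diag(theta0.eta, data.Lambda)
    r = data.Ytilde - data.Xtilde @ theta0.beta
    g = np.abs(data.Xtilde[:, 1:].T @ (w * r))
    with np.errstate(divide="ignore"):
        scaled = np.where(pen > 0, g / pen, 0.0)
    return float(scaled.max())


def lambda_sequence(lam_max: float, K: int = 100, tau: float = 0.01) -> np.ndarray:
    """K log-equally-spaced values decreasing from lam_max to tau*lam_max."""
    if lam_max <= 0:
        raise ValueError("lam_max must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    return np.geomspace(lam_max, tau * lam_max, K)


def gic(nll_value: float, df: int, N_T: int, p: int, a_n="hdbic") -> float:
    """Generalized information criterion 2*nll + a_n * df.

    ``a_n``: "hdbic" (default) -> log(log N_T) * log(p); "bic" -> log N_T;
    or any nonnegative number.
    """
    if df < 2:
        raise ValueError("df must be >= 2 (eta and sigma2 are always counted)")
    if isinstance(a_n, str):
        if a_n == "hdbic":
            if N_T <= np.e:
                raise ValueError("hdbic needs N_T > e")
            a = np.log(np.log(N_T)) * np.log(p)
        elif a_n == "bic":
            a = np.log(N_T)
        else:
            raise ValueError(f"unknown criterion {a_n!r}")
    else:
        a = float(a_n)
    return float(2.0 * nll_value + a * df)


def fit_path(data: RotatedData, pen_factors: np.ndarray | None = None,
             K: int = 100, tau: float | None = None, tol: float = 1e-5,
             max_iter: int = 1000, a_n="hdbic",
             lambdas: np.ndarray | None = None,
             update_variance: bool = True,
             init: ThetaState | None = None,
             max_support: int | None = None) -> PathResult:
    """Fit the full regularization path with warm starts.

    The sequence starts at lambda_max (where the support is empty by the KKT
    conditions) and decreases on the log scale to tau*lambda_max; each
    solution seeds the next lambda. ``tau`` defaults to 0.01 when n < p and
    0.001 otherwise. ``update_variance=False`` freezes (eta, sigma2) at the
    values in ``init`` (plain weighted lasso path for the comparators).

    The path stops early (and is truncated) once a fit saturates — support
    reaching the sample count or sigma2 hitting its numerical floor — or once
    the support exceeds ``max_support``; beyond that point the penalized
    likelihood has entered its degenerate interpolating regime and further
    fits carry no statistical information.
    """
    n, p = data.n, data.p
    if pen_factors is None:
        pen_factors = np.ones(p + 1)
        pen_factors[0] = 0.0
    pen_factors = np.asarray(pen_factors, dtype=float)
    if tau is None:
        tau = 0.01 if n < p else 0.001

    if init is None:
        theta = fit_null_kkt(data)
    else:
        theta = init.copy()
    if lambdas is None:
        lam_max = lambda_max(data, theta, pen_factors)
        if lam_max <= 0:
            lam_max = 1e-3  # all columns orthogonal to the null residual
        lambdas = lambda_sequence(lam_max, K=K, tau=tau)
    lambdas = np.asarray(lambdas, dtype=float)

    Xsq = data.Xtilde * data.Xtilde
    thetas, diags = [], []
    df = np.empty(lambdas.shape[0], dtype=int)
    nlls = np.empty(lambdas.shape[0])
    gics = np.empty(lambdas.shape[0])
    n_done = 0
    for i, lam in enumerate(lambdas):
        pen = PenaltySpec(lam=lam, penalty_factors=pen_factors)
        theta, d = fit_lambda(data, pen, theta, tol=tol, max_iter=max_iter,
                              update_variance=update_variance, _Xsq=Xsq)
        if update_variance:
            # report (and warm-start from) the exact ML variance components at
            # the fitted beta: the solver's working sigma2 absorbs the
            # scale-equivariant penalty term and is not the ML estimate
            eta_ml, s2_ml = profile_variance(theta.beta, data)
            theta = ThetaState(beta=theta.beta, eta=eta_ml, sigma2=s2_ml)
        thetas.append(theta)
        diags.append(d)
        df[i] = int(np.count_nonzero(theta.beta[1:])) + 2
        nlls[i] = nll(theta, data)
        gics[i] = gic(nlls[i], df[i], n, p, a_n=a_n)
        n_done = i + 1
        nnz = df[i] - 2
        if (nnz >= n - 1 or theta.sigma2 <= 10 * SIGMA2_FLOOR
                or (max_support is not None and nnz > max_support)):
            break
    k = n_done
    return PathResult(lambdas=lambdas[:k], thetas=thetas, df=df[:k],
                      nll=nlls[:k], gic=gics[:k], diagnostics=diags, n=n, p=p)


def select_gic(path: PathResult) -> int:
    """Index of the converged fit with minimum GIC; ties go to the largest lambda.

    Saturated fits (support size reaching the sample count, or sigma2 at the
    numerical floor) are excluded: there the likelihood is unbounded and the
    criterion is meaningless.
    """
    ok = path.converged.copy()
    sat = np.array([(d >= path.n) or (t.sigma2 <= 10 * SIGMA2_FLOOR)
                    for d, t in zip(path.df, path.thetas)])
    ok &= ~sat
    if not ok.any():
        raise ValueError("no converged, non-saturated fit on the path")
    g = np.where(ok, path.gic, np.inf)
    return int(np.argmin(g))  # argmin takes the first (largest-lambda) minimum
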