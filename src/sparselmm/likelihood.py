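"""Parameter container and the rotated negative log-likelihood / penalized objective.

Model: Y ~ N(X beta, eta*sigma2*Phi + (1-eta)*sigma2*I). In the eigenbasis of
Phi the covariance is diagonal with entries sigma2 * dtilde_i where
dtilde_i = 1 + eta*(Lambda_i - 1), giving the O(n) likelihood below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import RotatedData

ETA_MIN = 0.01
ETA_MAX = 0.99
SIGMA2_FLOOR = 1e-12

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ThetaState:
    """Full parameter vector Theta = (beta, eta, sigma2).

    ``beta[0]`` is the (unpenalized) intercept; ``eta`` is the heritability
    fraction of total variance ``sigma2`` attributed to the kinship component.
    """

    beta: np.ndarray
    eta: float
    sigma2: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if not (self.sigma2 > 0):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")

    def copy(self) -> "ThetaState":
        return ThetaState(self.beta.copy(), self.eta, self.sigma2)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.beta, [self.eta, self.sigma2]])


@dataclass
class PenaltySpec:
    """lambda and per-covariate penalty factors v_j (v_0 = 0: intercept free)."""

    lam: float
    penalty_factors: np.ndarray = None
    p: int = field(default=None)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.penalty_factors is None:
            if self.p is None:
                raise ValueError("give penalty_factors or p")
            v = np.ones(self.p + 1)
            v[0] = 0.0
            self.penalty_factors = v
        else:
            v = np.asarray(self.penalty_factors, dtype=float)
            if v[0] != 0.0:
                raise ValueError("penalty factor for the intercept must be 0")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError("penalty factors must be finite and >= 0")
            self.penalty_factors = v
            self.p = v.shape[0] - 1


def dtilde_diag(eta: float, Lambda: np.ndarray) -> np.ndarray:
    """Diagonal of V in the eigenbasis: 1 + eta * (Lambda_i - 1)."""
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    return 1.0 + eta * (np.asarray(Lambda, dtype=float) - 1.0)


def weights(eta: float, sigma2: float, Lambda: np.ndarray) -> np.ndarray:
    """Observation weights w_i = 1 / (sigma2 * (1 + eta*(Lambda_i - 1)))."""
    if not (sigma2 > 0):
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    return 1.0 / (sigma2 * dtilde_diag(eta, Lambda))


def nll(theta: ThetaState, data: RotatedData) -> float:
    """Exact negative log-likelihood of the rotated model (constant included).

    (n/2) log(2 pi sigma2) + (1/2) sum log dtilde_i
    + (1/2 sigma2) sum (Ytilde_i - Xtilde_i beta)^2 / dtilde_i
    """
    d = dtilde_diag(theta.eta, data.Lambda)
    r = data.Ytilde - data.Xtilde @ theta.beta
    n = data.n
    return float(0.5 * n * (_LOG_2PI + np.log(theta.sigma2))
                 + 0.5 * np.sum(np.log(d))
                 + 0.5 / theta.sigma2 * np.sum(r * r / d))


def l1_penalty(beta: np.ndarray, pen: PenaltySpec) -> float:
    return float(pen.lam * np.sum(pen.penalty_factors[1:] * np.abs(beta[1:])))


def objective(theta: ThetaState, data: RotatedData, pen: PenaltySpec) -> float:
    """Penalized objective Q_lambda(Theta) = nll + lambda * sum_j v_j |beta_j| / sigma2.

    The l1 term is measured relative to the current total variance (a
    scale-equivariant penalty in the spirit of Staedler et al.'s penalized
    mixture regression). This makes the beta-block stationarity conditions
    independent of sigma2 — the soft threshold a coordinate must beat does not
    shrink as the residual variance estimate falls along the path — which is
    what keeps the solver out of the degenerate interpolating basin that the
    unscaled penalty develops when p > n.
    """
    return nll(theta, data) + l1_penalty(theta.beta, pen) / theta.sigma2
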