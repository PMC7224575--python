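"""Random-effect (BLUP/MAP) and phenotype prediction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinship import KinshipSpectrum, RotatedData
from .likelihood import ThetaState, dtilde_diag


@dataclass
class PredictionInput:
    """Covariates and cross-kinship for a set of new individuals.

    ``X_star`` is q x (p+1) including the intercept column; ``Phi_star`` the
    q x n_train kinship between new and training individuals (None for
    fixed-effects-only prediction).
    """

    X_star: np.ndarray
    Phi_star: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_star = np.asarray(self.X_star, dtype=float)
        if self.Phi_star is not None:
            self.Phi_star = np.asarray(self.Phi_star, dtype=float)
            if not np.all(np.isfinite(self.Phi_star)):
                raise ValueError("Phi_star must be finite")
            if self.Phi_star.shape[0] != self.X_star.shape[0]:
                raise ValueError("X_star and Phi_star row counts differ")


def blup(theta: ThetaState, Y: np.ndarray, X: np.ndarray,
         spectrum: KinshipSpectrum) -> np.ndarray:
    """MAP estimate of the polygenic random effect b.

    Computed in the spectral form
        b_hat = U diag(Lambda_i / (Lambda_i + 1/eta)) U' (Y - X beta),
    which is algebraically equal to (I + (1/eta) Phi^-1)^-1 (Y - X beta) when
    Phi is invertible, and remains well defined for singular Phi.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    resid = Y - X @ theta.beta
    if theta.eta <= 0.0:
        return np.zeros_like(resid)
    shrink = spectrum.Lambda / (spectrum.Lambda + 1.0 / theta.eta)
    return spectrum.U @ (shrink * (spectrum.U.T @ resid))


def ranef_rotated_residual(theta: ThetaState, data: RotatedData,
                           spectrum: KinshipSpectrum) -> np.ndarray:
    """The training-sample vector g = U Dtilde^-1 (Ytilde - Xtilde beta).

    Phenotype prediction for new individuals is mu* = X* beta + eta * Phi* g,
    so ``g`` is all a fitted model needs to retain from the training data.
    """
    d = dtilde_diag(theta.eta, data.Lambda)
    r = (data.Ytilde - data.Xtilde @ theta.beta) / d
    return spectrum.U @ r


def predict_phenotype(theta: ThetaState, X_star: np.ndarray,
                      Phi_star: np.ndarray | None,
                      data: RotatedData, spectrum: KinshipSpectrum) -> np.ndarray:
    """Conditional-mean phenotype prediction for new individuals.

    mu* = X* beta + eta * Phi* U Dtilde^-1 (Ytilde - Xtilde beta), where
    ``Phi_star`` is the q x n_train kinship between new and training samples.
    With ``Phi_star=None`` the prediction is fixed effects only. A
    ``PredictionInput`` may be passed as ``X_star`` instead of the pair.
    """
    if isinstance(X_star, PredictionInput):
        Phi_star = X_star.Phi_star
        X_star = X_star.X_star
    X_star = np.asarray(X_star, dtype=float)
    if X_star.shape[1] != data.Xtilde.shape[1]:
        raise ValueError(
            f"X_star has {X_star.shape[1]} columns, training design has "
            f"{data.Xtilde.shape[1]}")
    mu = X_star @ theta.beta
    if Phi_star is not None:
        Phi_star = np.asarray(Phi_star, dtype=float)
        if Phi_star.shape != (X_star.shape[0], data.n):
            raise ValueError(
                f"Phi_star must be {(X_star.shape[0], data.n)}, got {Phi_star.shape}")
        mu = mu + theta.eta * (Phi_star @ ranef_rotated_residual(theta, data, spectrum))
    return mu
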