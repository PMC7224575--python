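"""Scikit-learn style estimator for the penalized kinship LMM.

``PenalizedKinshipLMM`` fits the whole regularization path of the lasso-penalized
linear mixed model with a single kinship random effect and keeps the fit at the
GIC-selected penalty. The kinship matrix (or the genotypes to estimate it from)
is passed to ``fit`` alongside ``X`` and ``y``; ``X`` holds the candidate
(penalized) covariates only — the intercept is handled internally.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .kinship import KinshipMatrix, estimate_kinship, rotate, spectral_decompose
from .path import fit_path, select_gic
from .prediction import ranef_rotated_residual


class PenalizedKinshipLMM(RegressorMixin, BaseEstimator):
    """Lasso-penalized linear mixed model with a single kinship random effect.

    Parameters
    ----------
    n_lambda : int
        Length of the regularization path (K).
    tau : float or None
        Ratio lambda_min / lambda_max; default 0.01 when n < p else 0.001.
    criterion : {"hdbic", "bic"} or float
        a_n of the generalized information criterion used for selection.
    penalty_factors : array of shape (p,) or None
        Per-covariate penalty multipliers (0 = unpenalized); default all ones.
    tol, max_iter : solver controls for each single-lambda fit.
    standardize : bool
        If True, columns of X are scaled to unit variance internally and the
        coefficients are returned on the original scale.

    Attributes
    ----------
    intercept_, coef_ : selected-model coefficients (original X scale).
    eta_, sigma2_ : variance components at the selected penalty.
    lambda_, lambda_index_ : selected penalty and its path position.
    path_ : PathResult with the per-lambda fits and GIC values.
    spectrum_ : KinshipSpectrum of the training kinship matrix.
    """

    def __init__(self, n_lambda: int = 100, tau: float | None = None,
                 criterion="hdbic", penalty_factors=None, tol: float = 1e-5,
                 max_iter: int = 1000, standardize: bool = False):
        self.n_lambda = n_lambda
        self.tau = tau
        self.criterion = criterion
        self.penalty_factors = penalty_factors
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    def fit(self, X, y, kinship=None, kinship_genotypes=None):
        """Fit the path and select a model by GIC.

        Exactly one of ``kinship`` (n x n matrix or KinshipMatrix) and
        ``kinship_genotypes`` (n x k dosage matrix, GRM estimated internally)
        must be given.
        """
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if (kinship is None) == (kinship_genotypes is None):
            raise ValueError("give exactly one of kinship / kinship_genotypes")
        if kinship_genotypes is not None:
            kin = estimate_kinship(np.asarray(kinship_genotypes))
        elif isinstance(kinship, KinshipMatrix):
            kin = kinship
        else:
            kin = KinshipMatrix(values=np.asarray(kinship, dtype=float),
                                n_snps_used=0)
        if kin.n != n:
            raise ValueError(f"kinship is {kin.n}x{kin.n} but X has {n} rows")

        scale = np.ones(p)
        Xw = X
        if self.standardize:
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            Xw = X / scale

        self.spectrum_ = spectral_decompose(kin)
        design = np.column_stack([np.ones(n), Xw])
        rot = rotate(y, design, self.spectrum_)

        if self.penalty_factors is not None:
            pf = np.concatenate([[0.0], np.asarray(self.penalty_factors, float)])
        else:
            pf = None
        self.path_ = fit_path(rot, pen_factors=pf, K=self.n_lambda,
                              tau=self.tau, tol=self.tol,
                              max_iter=self.max_iter, a_n=self.criterion)
        i = select_gic(self.path_)
        theta = self.path_.thetas[i]
        self.lambda_index_ = i
        self.lambda_ = float(self.path_.lambdas[i])
        self.gic_ = float(self.path_.gic[i])
        self.df_ = int(self.path_.df[i])
        self.theta_ = theta
        self.intercept_ = float(theta.beta[0])
        self.coef_ = theta.beta[1:] / scale
        self.eta_ = float(theta.eta)
        self.sigma2_ = float(theta.sigma2)
        self.n_features_in_ = p
        self._rotated = rot
        self._ranef_g = ranef_rotated_residual(theta, rot, self.spectrum_)
        return self

    def predict(self, X, kinship_cross=None):
        """Predict phenotypes; add the kinship term when ``kinship_cross``
        (q x n_train kinship between new and training samples) is given."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        mu = self.intercept_ + X @ self.coef_
        if kinship_cross is not None:
            K = check_array(kinship_cross)
            if K.shape != (X.shape[0], self._ranef_g.shape[0]):
                raise ValueError("kinship_cross has wrong shape")
            mu = mu + self.eta_ * (K @ self._ranef_g)
        return mu

    @property
    def selected_(self) -> np.ndarray:
        """Indices of the nonzero penalized coefficients."""
        check_is_fitted(self, "coef_")
        return np.flatnonzero(self.coef_)
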