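"""Kinship (GRM) estimation, spectral decomposition and eigenbasis rotation.

The model's covariance is V = eta * sigma2 * Phi + (1 - eta) * sigma2 * I.
Everything downstream works in the eigenbasis of Phi: with Phi = U diag(Lambda) U'
the rotated response Ytilde = U'Y and design Xtilde = U'X have a *diagonal*
covariance diag(sigma2 * (1 + eta * (Lambda_i - 1))), which is what makes the
penalized fit tractable at genome scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class KinshipMatrix:
    """A symmetric relatedness matrix estimated from genotypes.

    Attributes
    ----------
    values : ndarray of shape (n, n)
        Symmetric positive semi-definite (up to numerical noise) relatedness.
    n_snps_used : int
        Number of SNPs that passed filters and entered the estimate.
    sample_ids : list of str
        Sample identifiers in row/column order.
    """

    values: np.ndarray
    n_snps_used: int
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("kinship matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("kinship matrix is not symmetric")
        self.values = v
        if self.sample_ids and len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class KinshipSpectrum:
    """Eigendecomposition Phi = U diag(Lambda) U' with Lambda sorted descending."""

    U: np.ndarray
    Lambda: np.ndarray

    @property
    def n(self) -> int:
        return self.U.shape[0]


@dataclass
class RotatedData:
    """U-rotated response and design; the solver's working dataset.

    ``Xtilde`` column 0 is the rotated intercept column U'1. ``p`` counts the
    penalized covariates (columns 1..p of Xtilde).
    """

    Ytilde: np.ndarray
    Xtilde: np.ndarray
    Lambda: np.ndarray

    @property
    def n(self) -> int:
        return self.Ytilde.shape[0]

    @property
    def p(self) -> int:
        return self.Xtilde.shape[1] - 1


def standardize_genotypes(G: np.ndarray, min_maf: float = 0.01):
    """Mean-impute, MAF-filter and column-standardize a dosage matrix.

    Returns ``(G_std, kept)`` where columns are centered at 2*phat and scaled by
    sqrt(2*phat*(1-phat)) (the binomial standard deviation under HWE), and
    ``kept`` is the boolean mask of SNPs passing the filters.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x SNPs)")
    G = G.copy()
    # mean imputation of missing calls, per SNP
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
    phat = G.mean(axis=0) / 2.0
    kept = (phat >= min_maf) & (phat <= 1.0 - min_maf)
    # monomorphic columns have zero variance even if they pass the MAF window
    kept &= G.std(axis=0) > 0
    if not kept.any():
        raise ValueError("no informative SNPs: all SNPs monomorphic or below MAF filter")
    G = G[:, kept]
    p = phat[kept]
    G -= 2.0 * p
    G /= np.sqrt(2.0 * p * (1.0 - p))
    return G, kept


def estimate_kinship(G: np.ndarray, min_maf: float = 0.01,
                     sample_ids=None) -> KinshipMatrix:
    """Estimate the genomic relationship matrix Phi = G_s G_s' / k'.

    ``G`` holds dosages in {0, 1, 2} (NaN for missing) with samples in rows.
    Columns are standardized with sample allele frequencies; ``k'`` is the
    number of SNPs passing the MAF/polymorphism filters.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x SNPs)")
    if G.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate kinship")
    Gs, kept = standardize_genotypes(G, min_maf=min_maf)
    k_used = int(kept.sum())
    phi = (Gs @ Gs.T) / k_used
    phi = 0.5 * (phi + phi.T)
    return KinshipMatrix(values=phi, n_snps_used=k_used,
                         sample_ids=list(sample_ids) if sample_ids is not None else [])


def spectral_decompose(phi) -> KinshipSpectrum:
    """Eigendecompose a kinship matrix, repairing small negative eigenvalues.

    Eigenvalues below -1e-8 trigger a warning; all negative eigenvalues are
    clipped to zero so that the repaired matrix is PSD. Order is descending.
    """
    values = phi.values if isinstance(phi, KinshipMatrix) else np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("kinship matrix has non-finite entries")
    if values.shape[0] != values.shape[1] or np.max(np.abs(values - values.T)) > 1e-8:
        raise ValueError("kinship matrix must be symmetric")
    lam, U = scipy.linalg.eigh(values)
    if lam.min() < -1e-8:
        warnings.warn(
            f"kinship matrix has negative eigenvalues (min {lam.min():.3e}); "
            "clipping to 0 for PSD repair", RuntimeWarning)
    lam = np.clip(lam, 0.0, None)
    order = np.argsort(lam)[::-1]
    return KinshipSpectrum(U=np.ascontiguousarray(U[:, order]), Lambda=lam[order])


def rotate(Y: np.ndarray, X: np.ndarray, spectrum: KinshipSpectrum) -> RotatedData:
    """Rotate (Y, X) into the kinship eigenbasis: Ytilde = U'Y, Xtilde = U'X.

    ``X`` must already carry the intercept column of ones in column 0.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = spectrum.n
    if Y.shape[0] != n or X.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: spectrum has {n} samples, "
            f"Y has {Y.shape[0]}, X has {X.shape[0]} rows")
    Ut = spectrum.U.T
    return RotatedData(Ytilde=Ut @ Y, Xtilde=np.ascontiguousarray(Ut @ X),
                       Lambda=spectrum.Lambda)
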