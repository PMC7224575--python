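import numpy as np
import pytest

from sparselmm.kinship import RotatedData, estimate_kinship, rotate, spectral_decompose


def random_psd(n, rng, scale=1.0):
    """Random symmetric PSD matrix with unit-order diagonal."""
    A = rng.standard_normal((n, 2 * n))
    M = A @ A.T / (2 * n)
    return scale * 0.5 * (M + M.T)


def random_rotated_problem(n, p, rng, eta=0.3, sigma2=1.0, beta=None):
    """A small mixed-model dataset returned both raw and rotated.

    Y is drawn from N(X beta, eta*sigma2*Phi + (1-eta)*sigma2*I) with a
    random PSD kinship, so likelihood values can be cross-checked densely.
    """
    phi = random_psd(n, rng)
    spec = spectral_decompose(phi)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    if beta is None:
        beta = np.zeros(p + 1)
        beta[0] = rng.normal()
        if p:
            beta[1] = 1.0
    V = eta * sigma2 * phi + (1.0 - eta) * sigma2 * np.eye(n)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    Y = X @ beta + L @ rng.standard_normal(n)
    rot = rotate(Y, X, spec)
    return dict(phi=phi, spec=spec, X=X, Y=Y, rot=rot, beta=beta,
                eta=eta, sigma2=sigma2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
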