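"""Admixed genotype and structured phenotype simulation.

Genotypes follow a Balding-Nichols admixture model with 1-D geography:
ancestral frequencies p_anc ~ U(0.05, 0.95); subpopulation frequencies
Beta(p_anc(1-F)/F, (1-p_anc)(1-F)/F) with per-subpopulation differentiation F
ramped linearly along the line; individuals sit on the same line and draw
admixture proportions from a Gaussian kernel to the subpopulation centers.
Phenotypes follow Y = X beta + P + eps with P ~ N(0, eta*sigma2*Phi) (Phi the
GRM of the kinship SNPs) and eps ~ N(0, (1-eta)*sigma2*I).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import estimate_kinship, spectral_decompose

#: index of the per-module random streams spawned from the scenario seed
_STREAMS = {"geno_model": 0, "geno_kin": 1, "effects": 2, "phenotype": 3,
            "split": 4}


@dataclass
class SimScenario:
    """Declarative simulation configuration (the study conditions)."""

    n: int = 1000
    p: int = 5000
    k: int = 10000
    c: float = 0.01
    eta: float = 0.1
    sigma2: float = 1.0
    overlap: str = "none"  # "none" | "all"
    null_model: bool = False
    n_subpops: int = 10
    fst_min: float = 0.01
    fst_max: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.null_model:
            self.c = 0.0
        m = self.c * self.p
        if abs(m - round(m)) > 1e-9 or m < 0:
            raise ValueError("c * p must be a nonnegative integer")
        if round(m) > self.p:
            raise ValueError("more causal SNPs than model SNPs")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must be in [0, 1]")
        if self.overlap not in ("none", "all"):
            raise ValueError("overlap must be 'none' or 'all'")

    @property
    def n_causal(self) -> int:
        return int(round(self.c * self.p))

    def stream(self, name: str) -> np.random.Generator:
        """Per-component generator split deterministically from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[name]])


@dataclass
class SimDataset:
    """A realized dataset: genotypes, phenotype, and the generating truth."""

    X: np.ndarray            # n x p model-SNP dosages {0,1,2} (float)
    G_kin: np.ndarray        # n x k raw dosages for the kinship estimate
    Y: np.ndarray
    beta_true: np.ndarray    # on the raw-dosage scale
    causal_idx: np.ndarray
    subpop_labels: np.ndarray
    Phi: np.ndarray          # GRM of G_kin used to draw the polygenic effect
    scenario: SimScenario = field(repr=False, default=None)

    @property
    def X_raw(self) -> np.ndarray:
        return self.X


def _admixture_proportions(n: int, n_subpops: int) -> np.ndarray:
    """Row-stochastic admixture weights from a 1-D Gaussian geography kernel."""
    centers = np.arange(1.0, n_subpops + 1.0)
    x = np.linspace(centers[0], centers[-1], n)
    bw = 1.0 if n_subpops < 2 else centers[1] - centers[0]
    Q = np.exp(-0.5 * ((x[:, None] - centers[None, :]) / bw) ** 2)
    rows = Q.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("degenerate admixture kernel: all-zero weights")
    return Q / rows[:, None]


def simulate_admixture_genotypes(scenario: SimScenario, n_snps: int,
                                 rng: np.random.Generator):
    """Draw an n x n_snps dosage matrix from the BN-PSD model.

    Monomorphic SNPs are redrawn so every column is polymorphic. Returns
    ``(G, subpop_labels)`` with G of dtype int8 and labels the nearest
    subpopulation center of each individual.
    """
    sc = scenario
    Q = _admixture_proportions(sc.n, sc.n_subpops)
    F = np.linspace(sc.fst_min, sc.fst_max, sc.n_subpops)
    labels = np.argmax(Q, axis=1)

    G = np.empty((sc.n, n_snps), dtype=np.int8)
    todo = np.arange(n_snps)
    for _ in range(100):
        m = todo.size
        p_anc = rng.uniform(0.05, 0.95, size=m)
        shape1 = p_anc[None, :] * (1.0 - F[:, None]) / F[:, None]
        shape2 = (1.0 - p_anc[None, :]) * (1.0 - F[:, None]) / F[:, None]
        p_sub = rng.beta(shape1, shape2)            # n_subpops x m
        p_ind = np.clip(Q @ p_sub, 0.0, 1.0)        # n x m
        G[:, todo] = rng.binomial(2, p_ind).astype(np.int8)
        mono = G[:, todo].std(axis=0) == 0
        if not mono.any():
            break
        todo = todo[mono]
    else:  # pragma: no cover - essentially impossible for n >= 2
        raise RuntimeError("could not draw polymorphic SNPs")
    return G, labels


def assign_effects(scenario: SimScenario, rng: np.random.Generator):
    """Draw the causal set and effect sizes.

    Causal indices are uniform without replacement among the p model SNPs;
    causal effects are standard normal on the raw-dosage scale, so the
    fixed-effect genetic variance is ~ c*p * E[2p(1-p)] (about 17 at the
    default 1% of 5000 SNPs). Returns ``(beta_true, causal_idx,
    kinship_dup_idx)`` where the last entry lists the model columns duplicated
    into the kinship set (overlap='all') or empty.
    """
    m = scenario.n_causal
    beta = np.zeros(scenario.p)
    if m > 0:
        causal = np.sort(rng.choice(scenario.p, size=m, replace=False))
        beta[causal] = rng.standard_normal(m)
    else:
        causal = np.array([], dtype=int)
    dup = causal if (scenario.overlap == "all" and m > 0) else np.array([], dtype=int)
    return beta, causal, dup


def simulate_phenotype(X: np.ndarray, G_kin: np.ndarray,
                       beta_true: np.ndarray, scenario: SimScenario,
                       rng: np.random.Generator):
    """Draw Y = X beta + P + eps; returns (Y, Phi).

    ``X`` enters on its raw dosage scale. P is drawn through the spectral
    square root of the estimated GRM of the kinship SNPs (negative eigenvalues
    clipped), eps is iid Gaussian.
    """
    phi = estimate_kinship(G_kin)
    spec = spectral_decompose(phi)
    n = X.shape[0]
    sc = scenario
    P = spec.U @ (np.sqrt(sc.eta * sc.sigma2 * spec.Lambda) * rng.standard_normal(n))
    eps = rng.normal(0.0, np.sqrt((1.0 - sc.eta) * sc.sigma2), size=n)
    Y = np.asarray(X, dtype=float) @ beta_true + P + eps
    return Y, phi.values


def simulate_dataset(scenario: SimScenario) -> SimDataset:
    """Realize a full dataset for a scenario (deterministic given its seed).

    Under overlap='none' the k kinship SNPs are an independent draw, disjoint
    from the model SNPs; under overlap='all' the raw causal columns of X are
    placed inside the kinship set (replacing the last |S0| fresh SNPs).
    """
    sc = scenario
    X_raw, labels = simulate_admixture_genotypes(sc, sc.p, sc.stream("geno_model"))
    beta, causal, dup = assign_effects(sc, sc.stream("effects"))
    G_kin, _ = simulate_admixture_genotypes(sc, sc.k, sc.stream("geno_kin"))
    if dup.size:
        G_kin = G_kin.copy()
        G_kin[:, sc.k - dup.size:] = X_raw[:, dup]
    X = X_raw.astype(float)
    Y, Phi = simulate_phenotype(X, G_kin, beta, sc, sc.stream("phenotype"))
    return SimDataset(X=X, G_kin=G_kin, Y=Y, beta_true=beta,
                      causal_idx=causal, subpop_labels=labels, Phi=Phi,
                      scenario=sc)
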