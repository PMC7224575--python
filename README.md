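# sparselmm

Penalized linear mixed models for SNP selection under population structure.

Genome-wide association and polygenic-score models face two coupled problems:
the number of candidate variants far exceeds the sample size, and the samples
are related — through families, admixture or cryptic population structure —
so their phenotypes are correlated. Standard practice handles the two
problems separately (principal-component covariates, or a two-stage "fit a
null mixed model, then run a lasso on its residuals"), which can cost power
and produce false positives. `sparselmm` fits both at once: a linear mixed
model with a single kinship random effect and an l1 penalty on the SNP
effects, so variant selection and structure adjustment happen inside one
likelihood.

## Model

For phenotypes Y (n x 1), candidate-SNP dosages X (n x p, p >> n) and a
kinship matrix Phi estimated from genome-wide markers,

    Y | (beta, eta, sigma2)  ~  N( X beta,  eta * sigma2 * Phi + (1 - eta) * sigma2 * I )

where `eta` in [0, 1] is the narrow-sense heritability attributed to the
kinship component and `sigma2` the total residual variance. Writing
Phi = U diag(Lambda) U' and rotating everything by U' makes the covariance
diagonal, so each likelihood evaluation is O(n) after one eigendecomposition.
Estimation minimizes the penalized objective

    Q_lambda(beta, eta, sigma2) = -loglik + lambda * sum_j v_j |beta_j| / sigma2

by blockwise coordinate gradient descent (soft-thresholding sweeps for beta,
bounded scalar likelihood steps for eta, closed form for sigma2), over a
KKT-derived decreasing lambda sequence with warm starts. The tuning parameter
is chosen by a generalized information criterion, by default the
high-dimensional BIC penalty a_n = log(log n) * log(p) on
df = #nonzero coefficients + 2. Random effects are predicted by their
posterior mode and new-sample phenotypes by the conditional-normal mean.
See `docs/methods.md` for the full account, including why the l1 term is
scaled by sigma2.

The package also ships the two standard comparators (the two-stage
residual lasso and the PC-adjusted lasso), a Balding–Nichols admixture
simulator with 1-D geography, and a benchmark harness that reruns the whole
simulation-study design.

## Worked example

```python
import numpy as np
from sparselmm import PenalizedKinshipLMM, SimScenario, simulate_dataset

sim = simulate_dataset(SimScenario(n=500, p=1000, k=2000, c=0.01,
                                   eta=0.3, sigma2=1.0, seed=42))
model = PenalizedKinshipLMM().fit(sim.X, sim.Y, kinship_genotypes=sim.G_kin)
found = set(model.selected_) & set(sim.causal_idx.tolist())
print(f"selected {model.selected_.size} SNPs at lambda={model.lambda_:.2f}, "
      f"{len(found)}/{sim.causal_idx.size} causal recovered")
print(f"eta_hat={model.eta_:.3f}  sigma2_hat={model.sigma2_:.3f}  "
      f"df={model.df_}")
```

Output:

```
selected 8 SNPs at lambda=50.44, 8/10 causal recovered
eta_hat=0.174  sigma2_hat=1.307  df=10
```

Eight SNPs enter the GIC-selected model, all eight truly causal; the two
missed causal SNPs carry the smallest effects, which also explains the
residual variance slightly above the simulated 1.0. `model.predict(X_new)` gives
fixed-effect predictions; passing `kinship_cross=` adds the conditional-mean
polygenic term.

The same workflow is available from the shell:

```bash
sparselmm simulate --n 500 --p 1000 --k 2000 --causal-frac 0.01 --eta 0.3 \
    --seed 42 --out-prefix sim
sparselmm fit --genotypes sim.geno.tsv --phenotype sim.pheno.tsv \
    --kinship-genotypes sim.kinsnps.tsv --out-prefix fit
sparselmm predict --model-prefix fit --genotypes sim.geno.tsv --out pred.tsv
sparselmm benchmark --n 200 --p 300 --k 500 --n-reps 3 --seed 1 --out-prefix bm
```

Genotypes are read from tab-separated dosage tables or PLINK 1
.bed/.bim/.fam triplets; every command writes a JSON run summary with the
seed and a configuration hash, and identical invocations reproduce their
outputs bitwise.

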