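# Methods

## Model

`sparselmm` fits the single-random-effect linear mixed model

    Y ~ N( X beta,  V ),    V = eta * sigma2 * Phi + (1 - eta) * sigma2 * I,

with an l1 penalty on the p SNP coefficients (the intercept, and any
covariate given penalty factor 0, is unpenalized). `Phi` is a kinship
matrix; `eta` is the fraction of residual variance assigned to the
kinship-structured component (the narrow-sense heritability of what the
fixed effects do not explain) and `sigma2` the total residual variance in
phenotype units squared. The parameterization over the compact set
eta in [0, 1] is used rather than the variance-ratio form because bounded
scalar optimization over it is straightforward.

All computation happens in the eigenbasis of Phi: with
Phi = U diag(Lambda) U', the rotated response Ytilde = U'Y and design
Xtilde = U'X have diagonal covariance sigma2 * dtilde, where
dtilde_i = 1 + eta * (Lambda_i - 1). One dense n x n eigendecomposition per
kinship matrix buys O(n)-per-evaluation likelihoods; the approach therefore
targets cohorts up to roughly 10^4 samples.

## Kinship

The default estimator is the genomic relationship matrix (GRM):
mean-imputed dosages are centered at 2*phat and scaled by
sqrt(2*phat*(1-phat)) with sample allele frequencies (MAF filter 0.01), and
Phi = Gs Gs' / k. This is the de facto standard estimator; note that
different estimators differ in *scale* (a GRM has mean diagonal near 1,
ancestry-referenced coancestry estimators can be substantially larger), and
because eta and sigma2 trade off against the scale of Phi, fitted variance
components are only comparable across studies using the same estimator.
Small negative eigenvalues of an estimated kinship are clipped to zero
(with a warning) rather than rejected.

## Penalized objective and why the l1 term is scaled by sigma2

The objective is

    Q_lambda(Theta) = -loglik(beta, eta, sigma2) + lambda * sum_j v_j |beta_j| / sigma2 .

Scaling the penalty by sigma2 (in the spirit of Staedler, Buehlmann and
van de Geer's scale-equivariant l1 penalization) makes the beta-block
stationarity conditions independent of sigma2: a coordinate enters the model
when |sum_i Xtilde_ij r_i / dtilde_i| exceeds lambda * v_j, whatever the
current variance estimate. This matters because the unscaled penalty makes
the effective threshold proportional to the running sigma2 estimate. When
p > n the penalized likelihood always possesses a degenerate basin — an
interpolating beta with sigma2 -> 0 has unbounded likelihood at finite l1
cost — and with an unscaled penalty the threshold collapses together with
sigma2, producing a positive feedback that drags the whole path into that
basin as soon as the model starts absorbing signal. The sigma2-free
threshold removes the feedback; the degenerate basin still exists but is no
longer downhill from the statistical solution.

## Solver

Each lambda is fit by blockwise coordinate gradient descent:

1. **beta block.** Gauss–Seidel sweeps of exact coordinate minimizations,
   beta_j <- S_{lambda v_j}( sum_i w_i Xtilde_ij r_ij ) / sum_i w_i Xtilde_ij^2
   with relatedness weights w_i = 1/dtilde_i and the partial residual r_ij.
   Sweeps identify the working set and signs; because the admixture cline
   gives every SNP a loading on a shared direction, plain coordinate descent
   converges at a slow linear rate on the active set, so the block is
   finished by a conjugate-gradient solve of the active-set normal equations
   with signs held fixed (coordinates that would cross zero are clipped, a
   guard rolls the step back if the block objective would rise, and ordinary
   sweeps verify). The fixed point is exactly the coordinate-descent one;
   the acceleration only changes the route (verified against an independent
   lasso implementation to 1e-6).
2. **(eta, sigma2) block.** sigma2 has the closed-form ML value
   mean(r_i^2 / dtilde_i); profiling it out leaves a 1-D eta problem on
   [0.01, 0.99], minimized by bound-constrained local descent (L-BFGS-B)
   from the current iterate, guarded never to increase the likelihood. The
   step is local rather than global because the 1-D profile can be bimodal
   mid-path, with the second mode belonging to the degenerate regime; a
   standalone global (grid + Brent) eta update is available and is the right
   tool at a fixed beta, e.g. in the null fit.

Cycles repeat until ||Theta_{k+1} - Theta_k||_2 < tol (default 1e-5, max
1000 cycles). Every block step descends its own objective; the recorded
per-cycle trace of Q_lambda obeys, exactly,

    Q_k <= Q_{k-1} + max(0, lambda * P_k * (1/sigma2_k - 1/sigma2_{k-1}))

(see `FitDiagnostics.descent_violations`), i.e. it is strictly nonincreasing
except for the bounded rescaling of the
penalty term when the sigma2 block moves; with frozen variance components
(the comparator lassos) or lambda = 0 it is strictly nonincreasing. An
active-set strategy (full sweep every 10th cycle plus a verifying full
sweep before convergence is declared) and eta-cached coordinate curvatures
keep the cost per cycle near the cost of one active sweep.

## Regularization path, selection, reporting

The null model (all penalized coefficients zero) has closed forms for the
intercept and sigma2 at each eta, so the null fit profiles eta globally.
From its weights, lambda_max = max_j |(1/v_j) sum_i Xtilde_ij r_i /
dtilde_i| is the smallest penalty with an all-zero solution (the KKT
boundary), and the path is K = 100 values log-spaced down to tau *
lambda_max (tau = 0.01 for n < p, 0.001 otherwise), warm-starting each fit
at the previous solution. After each fit the reported (eta, sigma2) are
re-profiled to their exact ML values at the fitted beta — the solver's
internal sigma2 is a working quantity — and those values feed the
likelihood, the information criterion and the next warm start. The path
stops early once a fit saturates (support reaching n, or sigma2 at its
floor): beyond that point fits carry no statistical information, and such
fits are never eligible for selection.

Model selection minimizes GIC = 2 * nll + a_n * df over converged,
non-saturated fits, with df = #nonzero penalized coefficients + 2 (the two
variance parameters; the intercept is constant across models and excluded)
and a_n = log(log n) * log(p) ("high-dimensional BIC", the default) or
log(n) (BIC). Ties prefer the larger lambda. The likelihood includes its
2*pi constant so values are comparable to external computations.

## Prediction

Random effects are predicted by the posterior-mode (MAP) formula
b_hat = U diag(Lambda / (Lambda + 1/eta)) U' (Y - X beta_hat), evaluated in
spectral form so a singular Phi is handled. Phenotypes for new individuals
use the conditional-normal mean mu* = X* beta_hat + eta * Phi* U
dtilde^{-1} (Ytilde - Xtilde beta_hat), with Phi* the new-by-training
kinship block. The two formulas embody slightly different error-variance
conventions (sigma2 versus (1-eta)*sigma2 in the MAP exponent), so the
duplicated-individual identity between them holds exactly only as eta -> 0;
the conditional mean is the one used for prediction. Without Phi*,
prediction is fixed-effects only — the default in the benchmark's test-set
RMSE, which matches a test-RMSE of ~1.0 under the null model.

## Synthetic data

The generator emulates an admixed cohort: per-SNP ancestral frequencies
U(0.05, 0.95); Balding–Nichols subpopulation frequencies
Beta(p(1-F)/F, (1-p)(1-F)/F) for 10 subpopulations with differentiation F
ramped linearly 0.01–0.1 along a line; individuals evenly spaced on the
same line with admixture weights from a Gaussian kernel (bandwidth = the
inter-subpopulation spacing) to the subpopulation centers; genotypes
Binomial(2, admixture-weighted frequency), monomorphic columns redrawn.
Phenotypes follow Y = X beta + P + eps with P drawn through the spectral
square root of the GRM of the k kinship SNPs (scaled by eta*sigma2) and
iid eps (scaled by (1-eta)*sigma2). Under the no-overlap scenario the
kinship SNPs are an independent draw; under full overlap the raw causal
columns of X are placed inside the kinship set.

Causal effects are standard normal on the raw dosage scale,
beta_causal ~ N(0, 1). At the study's default 1% of 5000 SNPs this puts
Var(X beta) ≈ 50 * E[2p(1-p)] ≈ 17 on top of sigma2 = 1 — a strongly
heritable trait whose signal dwarfs the polygenic term. This choice is
pinned down by internal consistency of the reference study's summary
statistics (an intercept-only mixed model on such data shows an error
variance near 14, per-SNP detection power near 0.85, and coefficient
estimation errors of 2–3, all of which this scale reproduces and a
unit-variance budget cannot). One global seed drives counter-split
substreams for model genotypes, kinship genotypes, effects, phenotype noise
and the train/test split, so components are independently reproducible.

What the generator does not emulate: linkage disequilibrium between SNPs
(draws are independent given ancestry), related individuals in the
family-pedigree sense, genotyping error or missingness patterns, and
non-Gaussian phenotypes. Passing benchmarks on these data therefore speaks
to structure-confounded but LD-free selection; on real panels with dense LD
the selected sets will differ in composition.

## Benchmark harness

The harness reruns the simulation design: per replicate, simulate, split
80/20, estimate the kinship and its spectrum on the training individuals,
fit each method on training data, and score

- TPR at FPR <= 5%: along the method's path, the largest lambda whose false
  positive rate does not exceed 5% (and is closest to it); null scenarios
  score 0 by convention;
- model size under each method's default selection — GIC for the penalized
  LMM, 10-fold CV (minimum validation MSE, no 1-SE rule) for the
  comparators;
- test RMSE from refitting the selected support unpenalized (mixed model at
  lambda = 0 for the main method, OLS for comparators) and predicting the
  test split with fixed effects only;
- estimation error ||beta_hat - beta||^2 and the variance components.

The two-stage comparator fits an intercept-only mixed model by this
package's spectral ML (stage 1), subtracts the MAP random effect, and runs
a plain lasso on the conditional residuals; its error variance is reported
as (1-eta_hat)*sigma2_hat and its heritability as the stage-1 eta_hat. The
PC-lasso comparator adds the top 10 principal-component scores of the
kinship genotypes (taken from the GRM spectrum) as unpenalized covariates.
Both comparators reuse the CGD core with identity rotation and frozen
eta = 0, sigma2 = 1, which reduces it to a standard lasso. Covariates are
never standardized by default (an opt-in with back-transformed coefficients
exists on the estimator).

Paths in the harness are capped at 330 nonzero coefficients: the FPR cap
needs supports up to ~|S0| + 0.05 * (p - |S0|) ≈ 300 at p = 5000, and
larger supports only approach the degenerate tail. The acceptance script
uses 20 replicates per scenario cell at the reference n = 1000, p = 5000,
k = 10000 — about 15 CPU-minutes — rather than the reference study's 200
replicates; its reported Monte-Carlo spreads are wide relative to the
corresponding standard errors at 20 replicates, which is the tolerance the
acceptance tests use.

## Numerical choices and limitations

- eta is bounded to [0.01, 0.99]; flat eta profiles tie-break to the lower
  bound (the simpler iid model). sigma2 is floored at 1e-12 with a warning.
- Degenerate (zero rotated variance) columns keep coefficient 0.
- Coordinate order is the column order; solutions on well-conditioned
  problems are order-invariant within tolerance (tested).
- The dense eigendecomposition is O(n^3): not intended beyond ~10^4
  samples; no low-rank or out-of-core path is provided.
- Only the lasso penalty is implemented (per-covariate penalty factors
  allow adaptive-lasso-style weighting); no elastic net or group
  penalties, and no REML variant of the likelihood.
- GIC model selection is the package default; cross-validated selection is
  provided for the comparator lassos only.
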