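# Methods

## Model

For `n` traits observed on the same individuals the animal model is

    y_i = X_i β_i + u_i + ε_i ,           i = 1..n
    u = (u_1, ..., u_n) ~ MVN(0, G0 ⊗ K)
    ε = (ε_1, ..., ε_n) ~ MVN(0, R0 ⊗ I)

with `K` an individual relatedness matrix: the pedigree additive
relationship matrix `A` (tabular method; founders unrelated, diagonal
1 + F) or a genomic relationship matrix `M` (centered marker cross-product
over `2 Σ p(1−p)`, allele frequencies from the sample, per-marker mean
imputation of missing genotypes; no shrinkage).  All analyses here use an
identity incidence for the random effects and an intercept-only fixed part
unless a design is supplied.

## Reparameterization

Both trait covariance matrices are written as modified Cholesky (LDLᵀ)
factorizations `C = L diag(d) Lᵀ` with `L` unit lower triangular.  The
diagonal `d` holds transformed-scale variances (σ²_a for the genetic side,
σ²_e for the residual side) and the `n(n−1)/2` strictly-lower entries of
`L` are unconstrained dependency parameters (κ genetic, α residual),
serialized column-by-column: (1,2), (1,3), (2,3), …  The map is a
bijection between {positive variances, real dependencies} and symmetric
positive-definite matrices, so optimizers and samplers never leave the
valid region.  Equivalently, the observation vector is built by mixing
independent per-trait effect vectors through `W = L ⊗ I`; trait 2's
genetic part is `κ₁₂ a₁ + a₂`, and so on.  `decompose_cov` inverts the map
pivot-recursively (implemented via a rescaled Cholesky factor, identical
to the closed-form back-transform identities, e.g.
σ²_u2 = κ₁₂² σ²_a1 + σ²_a2, σ_u12 = κ₁₂ σ²_a1).

Trait order matters to the parameterization (not to the implied
covariance): input column order is preserved and documented, never
permuted internally.

## Collapsed likelihood

With Gaussian latent effects the marginal covariance of the trait-major
stacked data is `V(θ) = G0(θ) ⊗ K + R0(θ) ⊗ I`.  Writing `K = Q Λ Qᵀ` and
rotating each trait by `Qᵀ` block-diagonalizes `V` into `n_ind` blocks
`λ_j G0 + R0` of size `n × n`; one eigendecomposition per relationship
matrix (cached, negative eigenvalues clipped at 0 with tolerance 1e−8)
makes each likelihood evaluation O(n_ind · n³).  The restricted likelihood
is the Patterson–Thompson criterion
`−½[log|V| + log|XᵀV⁻¹X| + yᵀPy + (N−p) log 2π]`; fixed effects are
integrated exactly (flat-prior limit).  A finite-variance Gaussian prior
for β (default 1e6 when requested) is available and evaluated by Woodbury
identities on the same pieces.  Only complete cases are analyzed; rows
with a missing trait value are dropped and counted.

## Priors and posterior

Hyperparameter priors follow the reparametrized scale: inverse-Gamma with
shape 0.5 and **rate** 0.5 (density ∝ x^−3/2 e^−0.5/x) on every variance,
Gaussian mean 0, variance 10 on every dependency parameter.  The posterior
is evaluated on the transformed scale (log variances + raw dependencies)
including the log-Jacobian of the log transform.  The rate convention is
stated prominently because "inverse-Gamma(0.5, 0.5)" is ambiguous between
rate and scale conventions; with both parameters equal the two coincide
numerically, but the implementation fixes rate.

## Engines

**REML** — L-BFGS-B on the transformed scale from univariate-fit starting
values (per-trait two-parameter REML fits, dependencies 0), optionally
plus jittered restarts, followed by Newton polish with central-difference
gradient/Hessian until the gradient norm falls below 1e−5.  Non-converged
results are returned flagged, never silently.

**Laplace (INLA-style)** — because the latent field is Gaussian and
collapses exactly, the nested approximation reduces to a Laplace
approximation of the hyperparameter posterior.  The mode is found as
above; the Hessian uses central differences with step 1e−4.  Samples are
drawn from a multivariate-t (df 7) centered at the mode with the inverse
negative Hessian as scale and importance-weighted by the exact posterior.
The weighting removes the skew bias a pure Gaussian draw leaves in the
back-transformed variance means (measured at ~0.2 posterior SD on the
bundled designs against long reference chains), at the cost of one
posterior evaluation per sample; the heavier t tail keeps weights bounded
against the inverse-Gamma prior's exponential tail on the log scale.  The
importance effective sample size is reported in the diagnostics.

**MCMC** — random-walk Metropolis with per-coordinate proposal scales
initialized from the Laplace curvature (2.4/√d rule).  A global step
multiplier adapts in batches of 50 during burn-in toward ~30% acceptance
and is frozen afterwards to preserve detailed balance.  Acceptance below
5% flags the result.  Chains start at the posterior mode.

All engines report original-scale variances, covariances, correlations and
heritabilities (`h²_i = g_ii / (g_ii + r_ii)`).  Bayesian engines report
posterior means, kernel-density modes (Gaussian KDE, Silverman bandwidth)
and equal-tail 95% intervals from the (weighted) back-transformed samples.
Headline point conventions: REML plug-in, Laplace posterior mean, MCMC
posterior mode — matrix point estimates for downstream BLUP use the
posterior-mean matrices (means of PD matrices are PD).

## BLUP and accuracy

Henderson's mixed model equations are assembled densely with
`R⁻¹ = R0⁻¹ ⊗ I`, `G⁻¹ = G0⁻¹ ⊗ K⁻¹` and solved by direct factorization
(a few thousand unknowns at the bundled design's scale; the relative
residual of the normal equations must reach 1e−8).  EBVs are produced for
all pedigree members, phenotyped or not.  Accuracy is the per-trait
Pearson correlation between estimated and true breeding values; the
headline figure averages over traits, and study-level accuracy averages
over replicates.

## Simulated data

The generator reproduces a factorial mating design: `n_seed + n_pollen`
unrelated founders and one offspring per (seed, pollen) pair — 675
individuals at the default 25 × 25.  Phenotypes are `y = a + e` with
`a = P z_a`, `P Pᵀ = G0 ⊗ K` (computed as `chol(G0) ⊗ chol(K)` applied as
a matrix product, never materialized at full size) and `e = T z_e`,
`T Tᵀ = R0 ⊗ I`; one integer seed drives a replicate, replicate `r` of a
study uses `base_seed + r`.  Two bundled scenarios fix the study
conditions: a high-heritability design (G0 diagonal 1.0/1.5/2.5, all
covariances positive, h² = 0.50/0.60/0.71) and a low-heritability design
(G0 diagonal 5/7/10 with a negative covariance, R0 diagonal 20/28/35,
h² = 0.20/0.20/0.22); both default to 50 replicates and base seed 2015.

What the generator does *not* emulate: selection, assortative mating,
genotype-by-environment interaction, non-Gaussian traits, missing records
and marker-genotype simulation.  Passing recovery tests therefore shows
the estimators work under the model's own assumptions, not robustness to
their violation.

## Replicate studies and standardization

`run_replicate_study` fits the selected engines to every replicate and
tabulates point estimates, estimation errors (estimate − truth), implied
correlations and heritabilities with empirical 95% intervals (2.5/97.5
percentiles of the per-replicate point estimates — the "empirical
interval" reading), and BLUP accuracies; per-replicate engine failures
are recorded and skipped.  `standardize_and_rescale` z-scores each trait
and returns the exact rule `C_ij → s_i s_j C_ij` for mapping covariance
estimates back to trait units, the standard device when traits differ by
orders of magnitude in phenotypic variance.

## Problem sizes used in the shipped checks

The shipped test-suite studies run 30 replicates per scenario with MCMC
chains of 6 000 (2 000 burn-in) and 1 500 importance samples per Laplace
fit; the acceptance script uses 10 replicates with the REML engine.  These
sizes were chosen so that Monte-Carlo error is small relative to the
effects being checked: genetic-correlation point estimates have
per-replicate SD ≈ 0.2–0.3 under these designs, so means over fewer than
~30 replicates are dominated by sampling noise.  Engine cross-checks use a
single full-size dataset with longer chains.

## Known limitations

* Complete cases only; trait-specific record sets (different `n_i` per
  trait) are not yet supported.
* The Laplace engine requires a negative-definite Hessian at the mode; flat
  (non-identifiable) posteriors — e.g. `K = I`, where σ²_a and σ²_e enter
  only through their sum — raise an error rather than returning an
  arbitrary answer.
* Dense linear algebra throughout: fine to a few thousand individuals,
  not intended for national-evaluation scale.
* Sensitivity of the dependency-parameter priors to trait ordering is
  documented but not resolved; input order is preserved.
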