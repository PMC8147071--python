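# Methods

## The generative model

Each cell type is modelled independently. Marginally, gene *i*'s counts
follow one of Poisson(μ), ZIP(p, μ), NB(ψ, μ) or ZINB(p, ψ, μ), all stored
in a single record (`FittedMarginal`) in which Poisson and ZIP carry an
infinite-dispersion sentinel and Poisson and NB carry p = 0. The NB is
mean/size parameterised: variance of the count component is μ(1 + μ/ψ). The
marginal mean and variance are (1−p)μ and (1−p)μ(1 + μ/ψ + pμ).

Family selection is two-staged. A gene whose sample mean (n⁻¹Σx) is at
least its unbiased sample variance ((n−1)⁻¹Σ(x−x̄)²) is treated as
not over-dispersed and tested Poisson vs ZIP; otherwise NB vs ZINB. The
zero-inflated alternative is kept when 2(ℓ₁ − ℓ₀) exceeds the χ²₁ upper-α
quantile, α = 0.05 by default. The χ²₁ null is used deliberately even though
p = 0 sits on the parameter boundary; the test is therefore conservative
(measured false-positive rate ≈ 0.01 at nominal 0.05), which errs toward
the simpler family.

Ties in the dispersion check ("mean ≥ variance") go to the Poisson branch,
taking the inequality literally.

Dependence across genes is a Gaussian copula with correlation **R**.
Because counts are discrete the copula is not identifiable from the counts
alone; the distributional transform restores identifiability by smearing
each count's probability mass uniformly over [x, x+1):
u\* = v·F̂(x−1) + (1−v)·F̂(x), v ~ U[0,1]. The scores Φ⁻¹(u\*) are jointly
Gaussian under the model, and **R̂** is their sample covariance standardised
to unit diagonal. The link R = sin(πτ/2) to Kendall's tau provides both an
interpretation and an optional plug-in estimator (`corr_estimator="tau"`,
tau-b with tie correction); the plug-in is cheaper but not guaranteed PSD,
so the Gaussian-scores route is the default.

## Numerical choices

- **MLE optimisation.** NB and the zero-inflated fits run Nelder–Mead in
  (logit p, log ψ, log μ) from two starts: a method-of-moments start
  (ψ₀ = m²/(s²−m) clipped to [1e−2, 1e4]; p₀ = excess-zero fraction) and the
  nested simpler model's solution. Taking the best of both enforces the
  nested log-likelihood inequalities in practice.
- **Dispersion boundary.** ψ ≥ 1e8 is the infinite sentinel. Additionally,
  an NB "improvement" below 1e−4 log-likelihood over the Poisson fit is
  treated as the boundary optimum, because gammaln(x+ψ) − gammaln(ψ) loses
  about 1e−16·ψ·log ψ of precision at huge ψ and can fake such gains.
- **Degenerate genes.** An all-zero gene fits as p = 1, μ = 0 (generation
  emits zeros); the partition routes such genes to group 3 regardless.
- **Fallback chain.** If a zero-inflated fit fails or lands below its nested
  model, the nested parameters are reported at the boundary (p = 0); a
  per-gene fit failure inside model fitting degrades to Poisson with a
  logged warning rather than aborting the whole cell type.
- **Score clipping.** u\* is clipped into [1e−10, 1−1e−10] so the probit
  never overflows.
- **PSD repair.** The standardised score covariance is PSD up to float
  drift; eigenvalues below −1e−8 trigger clipping at zero followed by
  re-standardisation of the diagonal. Copula sampling likewise clips
  negative eigenvalues, so rank-deficient **R̂** (more genes than cells) is
  handled.
- **Quantile inversion.** marginal_quantile strips the zero-inflation mass
  analytically and inverts the count component with scipy's `ppf`
  (min{k : F(k) ≥ q}); it is verified against a brute-force CDF scan.

## Gene partition

Group 1 (copula): observed zero proportion < cutoff, default 0.8. Group 3
(always zero in synthetic data): expressed in fewer than three cells.
Group 2 (independent marginals): the remainder. A gene satisfying both the
group-1 and group-3 definitions — possible only when n < 15 so that
(n−2)/n < 0.8 — goes to group 3: a gene seen in under three cells is never
copula-modelled. With fewer than two cells no covariance exists, so the
model falls back to independent marginals with a warning.

## Generation and depth rescaling

Cell numbers per type are Multinomial(n′, π̂), π̂ the training proportions.
With N^(k)0 = (N^(k)/n^(k))·n^(k)′, the single scale factor
r = N′/Σ N^(s)0 multiplies every modelled gene's μ (group 2 included —
depth rescaling is a property of the protocol, not of the gene group);
p and ψ are left untouched, so the marginal variance is intentionally not
depth-invariant. N′ is an expected total: the realised grand total
fluctuates around it, mimicking sequencing randomness. Draw order is fixed
(types in registry order; per type the group-1 Gaussian block, then group-2
uniforms gene-major) and the generator is numpy's PCG64, pinned in the model
archive, so a seed reproduces bit-identically.

## What the fixtures emulate — and what they do not

`GroundTruthSpec` builds cell-type models from known parameters: a family
mix weighted toward NB/ZINB (the common case for UMI data), log-uniform
count means in [1, 50] for copula genes, sparse means in [0.02, 0.15] for
group-2 genes, dispersions in [0.5, 10], dropout weights in [0.1, 0.4], and
exchangeable/block/explicit correlation structures. These reproduce the
model's assumed structure exactly, which is the point: they isolate
estimator behaviour from model misspecification. They do not emulate
batch effects, cell-cycle or trajectory structure, ambient RNA, doublets,
or the heavy right tail of real gene-mean distributions — so passing tests
certify correct inference under the model, not goodness-of-fit to any real
protocol. The correlation-recovery experiment
(`correlation_recovery_experiment`) measures the tau-plug-in estimator's
MSE over the strict upper triangle across a grid of cell numbers n and gene
counts p (top-p by marginal mean), with 50 replicates by default — a
desk-scale rendition of the full 1000-replicate study; MSE levels 0.09 /
0.04 / 0.01 correspond to ±0.3 / ±0.2 / ±0.1 average error on the
correlation scale.

## Family identifiability

A true ZIP gene has marginal variance (1−p)μ(1+pμ) > mean, so the
dispersion check routes it to the NB-vs-ZINB branch, where the fit returns
ZINB with ψ → ∞ — the identical distribution under a different label.
Family recovery is therefore assessed on identifiability classes,
`canonical_family`: zero-inflated iff p̂ > 0.01, over-dispersed iff finite
ψ̂ with μ̂/ψ̂ ≥ 0.05 (count-component variance at least 5% above its mean).
Under that equivalence, fit-on-own-output recovery at n = 5000 is
effectively complete.

## Problem sizes and tolerances in the test suite

Simulation-backed assertions use 20–100 seeded replicates, n between 500
and 5000 cells, and 10–45 genes; parameter-recovery tolerances (10%
relative at n = 5000, ±0.05 on correlations at n = 2000) come from pilot
runs at those sizes and are comfortably above the corresponding standard
errors. The recovery-curve check uses n ∈ {20, 50, 100, 500} with 50
replicates and 10 genes.

## Known limitations

- Correlation estimation is dense; no sparsity or shrinkage for very large
  gene panels, so |group 1| in the thousands with few cells will be noisy
  (the recovery experiment quantifies exactly how noisy).
- Marginals are covariate-free: no pseudotime, batch or library-size
  covariates.
- The simulator generates counts only — no spatial coordinates, doublets,
  or exact-total-count (conditional) generation.
- **R̂** inherits extra randomness from the auxiliary uniforms v\*; the
  effect on synthetic data is negligible but **R̂** is not a deterministic
  function of the data unless the fitting RNG is seeded.
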