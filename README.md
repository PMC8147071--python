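# copulacount

A generative simulator for single-cell RNA-seq count matrices. Given a
gene-by-cell matrix of raw counts with a cell-type label per cell,
`copulacount` fits one probabilistic model per cell type — data-driven count
marginals for every gene coupled by a Gaussian copula — and then generates
synthetic count matrices at any user-chosen cell number *n′* and expected
sequencing depth *N′* while preserving each gene's count distribution and
the gene–gene correlation structure. It is aimed at computational biologists
who need realistic ground-truth data for benchmarking scRNA-seq methods
(clustering, rare-cell-type detection, differential expression) or for
planning experiments at depths and cell numbers they have not yet sequenced.

## Model

For one cell type with count matrix **X** ∈ ℕ^(p×n), each gene *i* is
modelled marginally by the best of four nested count families — Poisson,
zero-inflated Poisson (ZIP), negative binomial (NB), or zero-inflated
negative binomial ZINB(p_i, ψ_i, μ_i), where

- E(X | not dropped) = μ_i, Var(X | not dropped) = μ_i + μ_i²/ψ_i,
- a Bernoulli(p_i) dropout indicator adds a point mass at zero.

Genes without over-dispersion (sample mean ≥ sample variance) are tested
Poisson vs ZIP, the rest NB vs ZINB, using a likelihood-ratio test against
χ²₁ at α = 0.05. Joint dependence is a Gaussian copula: each count is mapped
to a Uniform(0,1) score by the distributional transform
u\*_ij = v\*_ij F̂_i(x_ij − 1) + (1 − v\*_ij) F̂_i(x_ij) with v\* ~ U[0,1],
and the copula correlation **R** is the unit-diagonal–standardised sample
covariance of the probit scores Φ⁻¹(u\*). **R** relates to Kendall's tau by
R_hl = sin(π τ_hl / 2); a tau plug-in estimator is available as an option.
To keep estimation stable, genes are partitioned by sparsity: copula
modelling for genes with zero proportion < 0.8, marginal-only modelling for
sparser genes, and all-zero generation for genes expressed in fewer than
three cells.

Generation draws per-type cell numbers from Multinomial(n′, π̂), rescales
every gene's mean by the type-independent factor r = N′ / Σ_k N^(k)0 with
N^(k)0 = (N^(k)/n^(k)) n^(k)′, then samples z ~ N(0, **R̂**) per cell and
inverts each coordinate through the rescaled marginal quantile. A
"no-copula" variant generates all genes independently.

## Worked example

```python
import numpy as np
from copulacount import (fit_cell_type_model, simulate_dataset,
                         ExperimentDesign, compare_matrices)

# X_real: a 45-gene x 1000-cell count matrix of one cell type
model = fit_cell_type_model(X_real, cell_type="goblet",
                            rng=np.random.default_rng(1))
print(model.partition.group1.size)   # 30 copula-modelled genes

X_synth, labels, plan = simulate_dataset(
    [model], ExperimentDesign(n_prime=2000, N_prime=2 * X_real.sum(), seed=2))
print(plan.scale_factor)             # 1.0  (double cells at double depth
                                     #       leaves per-cell depth unchanged)
report = compare_matrices(X_real[:, :500], X_synth[:, :500], top_k=20)
for stat, mse in report.mse.items():
    print(stat, mse)
```

On a matrix drawn from a known ground-truth model this prints, for example:

```
MSE mean             0.01823
MSE variance         56.16
MSE cv               0.2509
MSE gene_zero_prop   0.0001686
MSE pearson          0.002105
MSE kendall          0.001446
```

i.e. the synthetic data reproduce the held-out cells' gene-wise means, zero
proportions and pairwise correlations almost exactly (variance MSE is on the
squared-count scale, so 56 is small against gene variances in the hundreds).

The same workflow is available from the shell:

```
copulacount fit counts.tsv labels.tsv model.json
copulacount simulate model.json synth.tsv --n-prime 2000 --n-reads 1e6 --seed 1
copulacount evaluate counts.tsv synth.tsv report
```

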