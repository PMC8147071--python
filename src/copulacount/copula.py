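"""Gene partitioning, distributional transform, and copula correlation.

Counts are discrete, so the copula coupling the genes' marginals is not
identifiable from ranks alone.  The distributional transform resolves this:
with v ~ Uniform[0,1] drawn independently per entry,

    u* = v * F(x - 1) + (1 - v) * F(x)

is exactly Uniform[0,1] when F is the true marginal CDF.  Mapping u* through
the standard-normal quantile gives Gaussian scores whose sample covariance,
standardised to unit diagonal, estimates the Gaussian-copula correlation R.
An alternative plug-in estimator sin(pi * tau_b / 2) from the pairwise
Kendall's tau matrix is provided as an option; it is cheaper but not
guaranteed positive semidefinite.

Before fitting, genes are split into three groups by sparsity: group 1
(zero proportion below a cutoff, default 0.8) gets the full copula model,
group 2 gets independent marginals only, and group 3 (expressed in fewer
than three cells) is generated as all zeros.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .marginals import FittedMarginal, marginal_cdf, select_marginal

__all__ = [
    "GenePartition",
    "CopulaScores",
    "CellTypeModel",
    "FitConfig",
    "partition_genes",
    "distributional_transform",
    "estimate_copula_correlation",
    "tau_to_copula_corr",
    "kendall_tau_matrix",
    "tau_plugin_correlation",
    "fit_cell_type_model",
]

logger = logging.getLogger(__name__)

U_EPS = 1e-10
PSD_TOL = -1e-8


@dataclass(frozen=True)
class GenePartition:
    """Sparsity-based three-way split of gene indices."""

    group1: np.ndarray  # copula-modelled
    group2: np.ndarray  # independent marginals
    group3: np.ndarray  # always zero in synthetic data
    zero_cutoff: float = 0.8

    @property
    def n_genes(self) -> int:
        return self.group1.size + self.group2.size + self.group3.size


@dataclass(frozen=True)
class CopulaScores:
    u_star: np.ndarray  # |group1| x n, clipped into (0, 1)
    v_star: np.ndarray  # the auxiliary uniforms, kept for reproducibility

    def __post_init__(self) -> None:
        if self.u_star.shape != self.v_star.shape:
            raise ValueError("u_star and v_star shapes differ")


@dataclass
class FitConfig:
    zero_cutoff: float = 0.8
    alpha: float = 0.05
    corr_estimator: str = "gaussian"  # or "tau"


@dataclass
class CellTypeModel:
    """Fitted generative model for one cell type.

    ``marginals`` maps gene index (into ``gene_names``) to its fitted
    marginal, for every group-1 and group-2 gene; ``corr`` is the copula
    correlation over group-1 genes in partition order.  ``n_cells`` and
    ``total_count`` record the training submatrix's size and sequencing
    depth, needed later to allocate reads across cell types.
    """

    cell_type: str
    partition: GenePartition
    marginals: dict[int, FittedMarginal]
    corr: np.ndarray
    n_cells: int
    total_count: float
    gene_names: list[str] = field(default_factory=list)
    use_copula: bool = True


def partition_genes(X, zero_cutoff: float = 0.8) -> GenePartition:
    """Split genes by observed sparsity.

    group1: zero proportion < ``zero_cutoff``; group3: expressed (count > 0)
    in fewer than three cells; group2: the rest.  A gene matching both the
    group-1 and group-3 definitions (possible only at tiny n) goes to group3.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a genes x cells matrix with >= 1 cell")
    if not 0 < zero_cutoff <= 1:
        raise ValueError("zero_cutoff must be in (0, 1]")
    n = X.shape[1]
    expressed = (X > 0).sum(axis=1)
    zero_prop = 1.0 - expressed / n
    g3 = expressed < 3
    g1 = (zero_prop < zero_cutoff) & ~g3
    g2 = ~g1 & ~g3
    idx = np.arange(X.shape[0])
    return GenePartition(idx[g1], idx[g2], idx[g3], zero_cutoff)


def distributional_transform(
    X_g1, marginals: list[FittedMarginal], rng: np.random.Generator
) -> CopulaScores:
    """Map group-1 counts to (0,1) scores via the randomised CDF transform."""
    X_g1 = np.asarray(X_g1)
    if X_g1.ndim != 2 or X_g1.shape[0] != len(marginals):
        raise ValueError("need exactly one marginal per group-1 gene")
    v = rng.uniform(size=X_g1.shape)
    u = np.empty_like(v)
    for i, m in enumerate(marginals):
        lo = marginal_cdf(m, X_g1[i] - 1)
        hi = marginal_cdf(m, X_g1[i])
        u[i] = v[i] * lo + (1.0 - v[i]) * hi
    u = np.clip(u, U_EPS, 1.0 - U_EPS)
    return CopulaScores(u_star=u, v_star=v)


def _nearest_psd_corr(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to 0 and re-standardise the diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= PSD_TOL:
        return R
    vals = np.clip(vals, 0.0, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(R), 1e-300, None))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def estimate_copula_correlation(scores: CopulaScores) -> np.ndarray:
    """Correlation of the standard-normal scores Phi^{-1}(u*).

    The sample covariance of the Gaussian scores is standardised to unit
    diagonal, symmetrised, and PSD-repaired if floating-point drift produced
    a negative eigenvalue.
    """
    u = scores.u_star
    if np.any(u <= 0) or np.any(u >= 1):
        raise RuntimeError("u* scores must lie strictly inside (0, 1)")
    if u.shape[1] < 2:
        raise ValueError("need at least 2 cells to estimate a covariance")
    z = stats.norm.ppf(u)
    cov = np.cov(z)
    cov = np.atleast_2d(cov)
    d = np.sqrt(np.diag(cov))
    d[d == 0] = 1.0
    R = cov / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return _nearest_psd_corr(R)


def tau_to_copula_corr(tau):
    """Gaussian-copula correlation implied by Kendall's tau: sin(pi*tau/2)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau) > 1):
        raise ValueError("Kendall's tau must lie in [-1, 1]")
    out = np.sin(np.pi * tau / 2.0)
    return float(out) if out.ndim == 0 else out


def kendall_tau_matrix(X) -> np.ndarray:
    """Pairwise tie-corrected Kendall's tau-b across the rows of X."""
    X = np.asarray(X)
    p = X.shape[0]
    T = np.eye(p)
    for h in range(p):
        for l in range(h + 1, p):
            if np.ptp(X[h]) == 0 or np.ptp(X[l]) == 0:
                t = 0.0
            else:
                t = stats.kendalltau(X[h], X[l]).statistic
                if not np.isfinite(t):
                    t = 0.0
            T[h, l] = T[l, h] = t
    return T


def tau_plugin_correlation(X) -> np.ndarray:
    """Plug-in copula correlation sin(pi/2 * tau_b) from the rows of X.

    Cheaper than the Gaussian-scores route but not guaranteed PSD.
    """
    return tau_to_copula_corr(kendall_tau_matrix(X))


def fit_cell_type_model(
    X_k,
    cell_type: str = "cell_type",
    gene_names: list[str] | None = None,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CellTypeModel:
    """Fit the full per-cell-type model: partition, marginals, correlation.

    Marginals are selected per gene for groups 1 and 2; the copula
    correlation is estimated over group-1 genes only.  With fewer than two
    cells the copula cannot be estimated and the model falls back to
    independent marginals.
    """
    X_k = np.asarray(X_k)
    if X_k.ndim != 2:
        raise ValueError("X_k must be a genes x cells matrix")
    config = config or FitConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if gene_names is None:
        gene_names = [f"gene{i}" for i in range(X_k.shape[0])]
    part = partition_genes(X_k, config.zero_cutoff)
    marginals: dict[int, FittedMarginal] = {}
    for i in np.concatenate([part.group1, part.group2]):
        try:
            marginals[int(i)] = select_marginal(X_k[i], alpha=config.alpha)
        except Exception as exc:  # pragma: no cover - defensive per-gene guard
            logger.warning("fit failed for gene %s (%s); forcing Poisson",
                           gene_names[i], exc)
            from .marginals import fit_poisson
            marginals[int(i)] = fit_poisson(X_k[i])

    use_copula = True
    p1 = part.group1.size
    if X_k.shape[1] < 2:
        warnings.warn(
            f"cell type {cell_type!r}: fewer than 2 cells; "
            "falling back to independent marginals")
        use_copula = False
        corr = np.eye(p1)
    elif p1 == 0:
        corr = np.eye(0)
    elif config.corr_estimator == "tau":
        corr = _nearest_psd_corr(tau_plugin_correlation(X_k[part.group1]))
    else:
        scores = distributional_transform(
            X_k[part.group1], [marginals[int(i)] for i in part.group1], rng)
        corr = estimate_copula_correlation(scores)
    return CellTypeModel(
        cell_type=cell_type,
        partition=part,
        marginals=marginals,
        corr=corr,
        n_cells=X_k.shape[1],
        total_count=float(X_k.sum()),
        gene_names=list(gene_names),
        use_copula=use_copula,
    )
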