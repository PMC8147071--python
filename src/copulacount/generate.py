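"""Synthetic count generation at user-chosen cell number and depth.

Given fitted per-cell-type models, the experiment design specifies a target
cell number n' and an expected total count N'.  Cell numbers per type are
drawn Multinomial(n', pi_hat) with pi_hat the training type proportions; the
per-type expected depths N^(k)0 = (N^(k)/n^(k)) n^(k)' are rescaled by the
type-independent factor r = N' / sum_s N^(s)0, which multiplies every gene's
count-component mean mu (dispersion and zero-inflation are untouched, so
variance is not depth-invariant — a property of the model, kept on purpose).

Group-1 genes are coupled through the Gaussian copula: each synthetic cell
draws z ~ N(0, R_hat), maps coordinates through the standard-normal CDF and
then through the rescaled marginal quantile.  Group-2 genes are generated
independently from their rescaled marginals; group-3 genes are zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .copula import CellTypeModel
from .marginals import marginal_quantile

__all__ = [
    "ExperimentDesign",
    "AllocationPlan",
    "estimate_proportions",
    "draw_cell_type_counts",
    "make_allocation_plan",
    "generate_cell_type",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Target cell number n', expected total count N', and RNG seed."""

    n_prime: int
    N_prime: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prime < 1:
            raise ValueError("n_prime must be >= 1")
        if self.N_prime <= 0:
            raise ValueError("N_prime must be positive")


@dataclass(frozen=True)
class AllocationPlan:
    counts_per_type: np.ndarray  # n^(k)'
    depth_unscaled: np.ndarray   # N^(k)0
    depth_scaled: np.ndarray     # N^(k)'
    scale_factor: float          # r


def estimate_proportions(labels, type_order: list[str] | None = None) -> np.ndarray:
    """Training cell-type proportions pi_hat^(k) = n^(k) / n."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if type_order is None:
        type_order = sorted(set(labels.tolist()))
    counts = np.array([(labels == t).sum() for t in type_order], dtype=float)
    if counts.sum() != labels.size:
        raise ValueError("labels contain types absent from type_order")
    return counts / labels.size


def draw_cell_type_counts(n_prime: int, proportions,
                          rng: np.random.Generator) -> np.ndarray:
    """Multinomial(n', pi_hat) draw of synthetic cell numbers per type."""
    proportions = np.asarray(proportions, dtype=float)
    if n_prime < 1:
        raise ValueError("n_prime must be >= 1")
    if np.any(proportions < 0) or abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    return rng.multinomial(n_prime, proportions)


def make_allocation_plan(models: list[CellTypeModel], counts_per_type,
                         N_prime: float) -> AllocationPlan:
    """Depth bookkeeping: N^(k)0, the scale factor r, and N^(k)' = r N^(k)0."""
    counts_per_type = np.asarray(counts_per_type, dtype=np.int64)
    if len(models) != counts_per_type.size:
        raise ValueError("one cell count per model required")
    if counts_per_type.sum() == 0:
        raise ValueError("at least one synthetic cell is required")
    for m in models:
        if m.n_cells < 1:
            raise ValueError(f"model {m.cell_type!r} has no training cells")
    depth0 = np.array(
        [m.total_count / m.n_cells * nk
         for m, nk in zip(models, counts_per_type)])
    r = float(N_prime / depth0.sum())
    return AllocationPlan(counts_per_type, depth0, r * depth0, r)


def _sample_gaussian_copula(R: np.ndarray, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """n draws from N(0, R) via eigendecomposition; tolerates rank deficiency."""
    vals, vecs = np.linalg.eigh(R)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    eps = rng.standard_normal(size=(R.shape[0], n))
    return root @ eps


def generate_cell_type(model: CellTypeModel, n_cells_out: int,
                       scale_factor: float, rng: np.random.Generator,
                       use_copula: bool = True) -> np.ndarray:
    """Synthetic genes x cells submatrix for one cell type.

    Draw order is fixed: the group-1 Gaussian block first, then group-2
    marginal uniforms gene-major, so a seeded generator reproduces exactly.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if n_cells_out < 0:
        raise ValueError("n_cells_out must be nonnegative")
    p = len(model.gene_names)
    X = np.zeros((p, n_cells_out), dtype=np.int64)
    if n_cells_out == 0:
        return X
    part = model.partition
    copula_on = use_copula and model.use_copula and part.group1.size > 0
    if copula_on:
        z = _sample_gaussian_copula(model.corr, n_cells_out, rng)
        u = stats.norm.cdf(z)
        u = np.clip(u, 0.0, 1.0 - 1e-16)
        for row, i in enumerate(part.group1):
            m = model.marginals[int(i)].rescaled(scale_factor)
            X[i] = marginal_quantile(m, u[row])
        independent = part.group2
    else:
        independent = np.concatenate([part.group1, part.group2])
    for i in independent:
        m = model.marginals[int(i)].rescaled(scale_factor)
        u = rng.uniform(size=n_cells_out)
        u = np.clip(u, 0.0, 1.0 - 1e-16)
        X[i] = marginal_quantile(m, u)
    return X


def simulate_dataset(models: list[CellTypeModel], design: ExperimentDesign,
                     use_copula: bool = True,
                     proportions=None):
    """Full synthetic dataset across all cell types.

    Returns ``(counts, labels, plan)``: a genes x n' integer matrix with
    columns grouped by type in model-registry order, the per-column type
    labels, and the allocation plan used.  Training proportions default to
    each model's share of training cells.
    """
    if not models:
        raise ValueError("at least one fitted model is required")
    genes0 = models[0].gene_names
    for m in models[1:]:
        if m.gene_names != genes0:
            raise ValueError("all models must share one gene list")
    rng = np.random.default_rng(design.seed)
    if proportions is None:
        tot = sum(m.n_cells for m in models)
        proportions = np.array([m.n_cells / tot for m in models])
    nk = draw_cell_type_counts(design.n_prime, proportions, rng)
    plan = make_allocation_plan(models, nk, design.N_prime)
    blocks, labels = [], []
    for m, k in zip(models, nk):
        blocks.append(generate_cell_type(m, int(k), plan.scale_factor, rng,
                                         use_copula=use_copula))
        labels.extend([m.cell_type] * int(k))
    return np.concatenate(blocks, axis=1), np.array(labels), plan
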