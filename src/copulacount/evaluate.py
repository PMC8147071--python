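"""Benchmarking statistics comparing a real and a synthetic count matrix.

Eight summary statistics: gene-wise mean, variance, coefficient of variation
and zero proportion; cell-wise zero proportion and library size; and
gene-pair-wise Pearson correlation and Kendall's tau-b.  Pair statistics are
restricted to genes whose zero proportion is below 0.5 (correlations of
near-silent genes are dominated by ties and carry little signal), optionally
further restricted to the top-k genes by mean expression in the real matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "GENE_STATS",
    "CELL_STATS",
    "PAIR_STATS",
    "MatrixStats",
    "EvalReport",
    "summary_statistics",
    "stat_mse",
    "correlation_matrix",
    "compare_matrices",
]

GENE_STATS = ("mean", "variance", "cv", "gene_zero_prop")
CELL_STATS = ("cell_zero_prop", "library_size")
PAIR_STATS = ("pearson", "kendall")

PAIR_ZERO_PROP_CUTOFF = 0.5


@dataclass
class MatrixStats:
    """Summary-statistic bundle for one matrix."""

    gene: pd.DataFrame   # index: gene names; columns: GENE_STATS
    cell: pd.DataFrame   # index: cell names; columns: CELL_STATS
    pair: pd.DataFrame   # index: (gene_a, gene_b); columns: PAIR_STATS
    pair_genes: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    real: MatrixStats
    synthetic: MatrixStats
    mse: dict[str, float]
    gene_subset_used: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mse": self.mse,
                       "gene_subset_used": self.gene_subset_used}, fh, indent=2)

    def to_tsv(self, prefix) -> None:
        self.real.gene.to_csv(f"{prefix}.real_gene.tsv", sep="\t")
        self.synthetic.gene.to_csv(f"{prefix}.synthetic_gene.tsv", sep="\t")
        self.real.cell.to_csv(f"{prefix}.real_cell.tsv", sep="\t")
        self.synthetic.cell.to_csv(f"{prefix}.synthetic_cell.tsv", sep="\t")
        pd.Series(self.mse, name="mse").to_csv(f"{prefix}.mse.tsv", sep="\t")


def _tau_b(x, y) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    t = stats.kendalltau(x, y).statistic
    return float(t) if np.isfinite(t) else 0.0


def _pearson(x, y) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def summary_statistics(X, gene_names=None, cell_names=None,
                       pair_genes: list[str] | None = None,
                       log_scale: bool = False) -> MatrixStats:
    """All eight statistics for one genes x cells count matrix.

    ``pair_genes`` fixes the gene set for pair statistics (so two matrices
    can be compared over identical pairs); by default it is the genes with
    zero proportion below 0.5.  With ``log_scale`` the mean, variance and
    library size are reported as log10(1 + x), mirroring common plotting
    practice.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a nonempty genes x cells matrix")
    p, n = X.shape
    gene_names = list(gene_names) if gene_names is not None else [
        f"gene{i}" for i in range(p)]
    cell_names = list(cell_names) if cell_names is not None else [
        f"cell{j}" for j in range(n)]

    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1) if n > 1 else np.zeros(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, np.nan)
    gene_zero = (X == 0).mean(axis=1)
    gene = pd.DataFrame(
        {"mean": mean, "variance": var, "cv": cv, "gene_zero_prop": gene_zero},
        index=gene_names)

    cell = pd.DataFrame(
        {"cell_zero_prop": (X == 0).mean(axis=0),
         "library_size": X.sum(axis=0).astype(float)},
        index=cell_names)

    if pair_genes is None:
        pair_genes = [g for g, z in zip(gene_names, gene_zero)
                      if z < PAIR_ZERO_PROP_CUTOFF]
    gidx = {g: i for i, g in enumerate(gene_names)}
    rows = []
    for ga, gb in combinations(pair_genes, 2):
        xa, xb = X[gidx[ga]], X[gidx[gb]]
        rows.append((ga, gb, _pearson(xa, xb), _tau_b(xa, xb)))
    pair = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pearson", "kendall"])
    pair = pair.set_index(["gene_a", "gene_b"]) if len(rows) else pd.DataFrame(
        columns=["pearson", "kendall"])

    if log_scale:
        gene["mean"] = np.log10(1 + gene["mean"])
        gene["variance"] = np.log10(1 + gene["variance"])
        cell["library_size"] = np.log10(1 + cell["library_size"])
    return MatrixStats(gene=gene, cell=cell, pair=pair, pair_genes=list(pair_genes))


def stat_mse(real_stats: MatrixStats, synth_stats: MatrixStats,
             statistic: str) -> float:
    """Mean-squared error of one statistic between two aligned matrices.

    Gene-wise statistics average over genes (cv entries undefined in either
    matrix are dropped); pair statistics average over unordered gene pairs.
    """
    if statistic in GENE_STATS:
        a = real_stats.gene[statistic].to_numpy()
        b = synth_stats.gene[statistic].to_numpy()
        if not real_stats.gene.index.equals(synth_stats.gene.index):
            raise ValueError("gene sets are not aligned")
        ok = np.isfinite(a) & np.isfinite(b)
        return float(np.mean((a[ok] - b[ok]) ** 2))
    if statistic in PAIR_STATS:
        if not real_stats.pair.index.equals(synth_stats.pair.index):
            raise ValueError("pair sets are not aligned")
        a = real_stats.pair[statistic].to_numpy()
        b = synth_stats.pair[statistic].to_numpy()
        return float(np.mean((a - b) ** 2))
    raise ValueError(f"unknown statistic {statistic!r}")


def correlation_matrix(X, gene_names, gene_list, measure: str = "pearson",
                       return_order: bool = False):
    """Symmetric, unit-diagonal correlation matrix over ``gene_list``.

    Pairs involving a zero-variance gene are set to 0.  Optionally also
    returns a complete-linkage ordering of the genes on 1 - correlation
    distance, the conventional heatmap ordering.
    """
    X = np.asarray(X)
    gidx = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in gene_list if g not in gidx]
    if missing:
        raise ValueError(f"unknown genes: {missing[:5]}")
    sub = X[[gidx[g] for g in gene_list]]
    k = len(gene_list)
    R = np.eye(k)
    fn = _pearson if measure == "pearson" else _tau_b
    if measure not in ("pearson", "kendall"):
        raise ValueError(f"unknown measure {measure!r}")
    for a in range(k):
        for b in range(a + 1, k):
            R[a, b] = R[b, a] = fn(sub[a], sub[b])
    if not return_order:
        return R
    if k < 3:
        return R, list(range(k))
    dist = squareform(np.clip(1.0 - R, 0.0, 2.0), checks=False)
    order = hierarchy.leaves_list(hierarchy.linkage(dist, method="complete"))
    return R, list(order)


def top_expressed_genes(real_stats: MatrixStats, k: int) -> list[str]:
    """Top-k genes by mean expression among the pair-eligible genes."""
    means = real_stats.gene.loc[real_stats.pair_genes, "mean"]
    return means.sort_values(ascending=False, kind="stable").index[:k].tolist()


def compare_matrices(X_real, X_synth, gene_names=None, top_k: int | None = 500,
                     log_scale: bool = False) -> EvalReport:
    """Full evaluation report between a real and a synthetic matrix.

    Both matrices must carry the same genes in the same order.  Pair MSEs use
    the real matrix's pair-eligible genes (zero proportion < 0.5), optionally
    narrowed to the ``top_k`` most highly expressed.
    """
    X_real = np.asarray(X_real)
    X_synth = np.asarray(X_synth)
    if X_real.shape[0] != X_synth.shape[0]:
        raise ValueError("matrices must carry identical, aligned gene sets")
    real0 = summary_statistics(X_real, gene_names, log_scale=log_scale)
    pair_genes = real0.pair_genes
    rule = f"zero proportion < {PAIR_ZERO_PROP_CUTOFF}"
    if top_k is not None and len(pair_genes) > top_k:
        pair_genes = top_expressed_genes(real0, top_k)
        rule += f", top {top_k} by real mean expression"
    real = summary_statistics(X_real, gene_names, pair_genes=pair_genes,
                              log_scale=log_scale)
    synth = summary_statistics(X_synth, gene_names, pair_genes=pair_genes,
                               log_scale=log_scale)
    mse = {s: stat_mse(real, synth, s) for s in GENE_STATS + PAIR_STATS}
    return EvalReport(real=real, synthetic=synth, mse=mse,
                      gene_subset_used={"genes": pair_genes, "rule": rule})
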