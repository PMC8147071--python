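"""Count-matrix and model-archive I/O.

Count matrices are genes x cells, either MatrixMarket triplet (.mtx) with
``genes.tsv`` / ``barcodes.tsv`` sidecars or dense delimited text with gene
rows and a header of cell names.  Only raw nonnegative-integer counts are
accepted: the generative model is defined on counts, so normalised or
continuous matrices are rejected rather than silently rounded.

Fitted models serialise to a versioned JSON archive that round-trips every
parameter bit-exactly (floats are written with shortest-repr precision).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .copula import CellTypeModel, GenePartition
from .marginals import Family, FittedMarginal

__all__ = [
    "CountMatrix",
    "ModelArchive",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "save_model",
    "load_model",
]

ARCHIVE_FORMAT_VERSION = 1
RNG_ALGORITHM = "numpy-PCG64"


@dataclass
class CountMatrix:
    """Genes x cells nonnegative-integer matrix with names and labels."""

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    cell_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        p, n = self.values.shape
        if len(self.gene_names) != p or len(self.cell_names) != n:
            raise ValueError("name lengths do not match matrix dimensions")
        if len(set(self.gene_names)) != p or len(set(self.cell_names)) != n:
            raise ValueError("gene and cell names must be unique")
        if self.cell_labels is not None and len(self.cell_labels) != n:
            raise ValueError("one label per cell required")
        _validate_counts(self.values)
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_label(self, label: str) -> "CountMatrix":
        if self.cell_labels is None:
            raise ValueError("matrix carries no cell labels")
        keep = [j for j, lab in enumerate(self.cell_labels) if lab == label]
        if not keep:
            raise ValueError(f"no cells labelled {label!r}")
        return CountMatrix(self.values[:, keep], self.gene_names,
                           [self.cell_names[j] for j in keep],
                           [label] * len(keep))


def _validate_counts(values) -> None:
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise ValueError(
            "matrix contains non-integer entries; this tool models raw "
            "counts and will not round a normalised matrix")


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Load a count matrix from .mtx + sidecars or dense delimited text."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "dense"
    if fmt == "mtx":
        genes_path = path.with_name("genes.tsv")
        cells_path = path.with_name("barcodes.tsv")
        for sidecar in (genes_path, cells_path):
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"missing sidecar {sidecar.name} next to {path.name}")
        M = spio.mmread(path)
        values = np.asarray(M.todense() if sparse.issparse(M) else M)
        gene_names = genes_path.read_text().splitlines()
        cell_names = cells_path.read_text().splitlines()
        if len(gene_names) != values.shape[0] or len(cell_names) != values.shape[1]:
            raise ValueError("sidecar lengths do not match matrix dimensions")
    elif fmt == "dense":
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy()
        gene_names = [str(g) for g in df.index]
        cell_names = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CountMatrix(values, gene_names, cell_names)


def write_counts(matrix: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a count matrix as .mtx + sidecars or dense delimited text."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "dense"
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(matrix.values), field="integer")
        path.with_name("genes.tsv").write_text(
            "\n".join(matrix.gene_names) + "\n")
        path.with_name("barcodes.tsv").write_text(
            "\n".join(matrix.cell_names) + "\n")
    elif fmt == "dense":
        sep = "," if path.suffix == ".csv" else "\t"
        pd.DataFrame(matrix.values, index=matrix.gene_names,
                     columns=matrix.cell_names).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path) -> dict[str, str]:
    """Two-column delimited file (cell name, type) -> mapping."""
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    if df.shape[1] < 2:
        raise ValueError("label file must have two columns: cell, type")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_labels(matrix: CountMatrix, path) -> None:
    if matrix.cell_labels is None:
        raise ValueError("matrix carries no cell labels")
    with open(path, "w") as fh:
        for cell, lab in zip(matrix.cell_names, matrix.cell_labels):
            fh.write(f"{cell}\t{lab}\n")


@dataclass
class ModelArchive:
    """Versioned container for fitted models plus fitting provenance."""

    models: list[CellTypeModel]
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    format_version: int = ARCHIVE_FORMAT_VERSION


def _float_or_inf(x: float):
    return "inf" if math.isinf(x) else x


def _marginal_to_dict(m: FittedMarginal) -> dict:
    return {"family": m.family.value, "pi_zero": m.pi_zero,
            "psi": _float_or_inf(m.psi), "mu": m.mu,
            "loglik": None if math.isnan(m.loglik) else m.loglik,
            "n_obs": m.n_obs}


def _marginal_from_dict(d: dict) -> FittedMarginal:
    psi = math.inf if d["psi"] == "inf" else float(d["psi"])
    loglik = float("nan") if d["loglik"] is None else float(d["loglik"])
    return FittedMarginal(Family(d["family"]), float(d["pi_zero"]), psi,
                          float(d["mu"]), loglik, int(d["n_obs"]))


def _model_to_dict(m: CellTypeModel) -> dict:
    return {
        "cell_type": m.cell_type,
        "gene_names": m.gene_names,
        "partition": {
            "group1": m.partition.group1.tolist(),
            "group2": m.partition.group2.tolist(),
            "group3": m.partition.group3.tolist(),
            "zero_cutoff": m.partition.zero_cutoff,
        },
        "marginals": {str(i): _marginal_to_dict(fm)
                      for i, fm in sorted(m.marginals.items())},
        "corr": np.asarray(m.corr).tolist(),
        "n_cells": m.n_cells,
        "total_count": m.total_count,
        "use_copula": m.use_copula,
    }


def _model_from_dict(d: dict) -> CellTypeModel:
    part = GenePartition(
        np.asarray(d["partition"]["group1"], dtype=int),
        np.asarray(d["partition"]["group2"], dtype=int),
        np.asarray(d["partition"]["group3"], dtype=int),
        float(d["partition"]["zero_cutoff"]))
    return CellTypeModel(
        cell_type=d["cell_type"],
        partition=part,
        marginals={int(i): _marginal_from_dict(fm)
                   for i, fm in d["marginals"].items()},
        corr=np.asarray(d["corr"], dtype=float).reshape(
            len(d["partition"]["group1"]), len(d["partition"]["group1"])),
        n_cells=int(d["n_cells"]),
        total_count=float(d["total_count"]),
        gene_names=list(d["gene_names"]),
        use_copula=bool(d["use_copula"]),
    )


def make_provenance(input_path=None) -> dict:
    prov = {"timestamp": datetime.now(timezone.utc).isoformat(),
            "rng_algorithm": RNG_ALGORITHM}
    if input_path is not None:
        digest = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
        prov["input_sha256"] = digest
        prov["input_path"] = str(input_path)
    return prov


def save_model(archive: ModelArchive, path) -> None:
    payload = {
        "format_version": archive.format_version,
        "config": archive.config,
        "provenance": archive.provenance,
        "models": [_model_to_dict(m) for m in archive.models],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> ModelArchive:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"archive format version {version!r} is not supported "
            f"(expected {ARCHIVE_FORMAT_VERSION})")
    return ModelArchive(
        models=[_model_from_dict(d) for d in payload["models"]],
        config=payload.get("config", {}),
        provenance=payload.get("provenance", {}),
        format_version=version,
    )
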