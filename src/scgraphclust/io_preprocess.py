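"""Loading and preprocessing of gene-by-cell expression matrices.

The preprocessing pipeline is fixed in order: low-expression gene
filtering, high-variance feature selection, then normalization.  Each
step stamps the matrix with a ``stage`` so that out-of-order use is an
error rather than a silent mistake.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)


class Stage(str, Enum):
    RAW = "raw"
    FILTERED = "filtered"
    SELECTED = "selected"
    NORMALIZED = "normalized"


class StageError(ValueError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass
class NormalizationConfig:
    """Which of the three normalization sub-steps to apply.

    size_factor : scale each cell's counts to the median library size
    log1p       : natural-log transform ``log(1 + v)``
    zscore      : per-gene standardization across cells
    """

    size_factor: bool = True
    log1p: bool = True
    zscore: bool = True


@dataclass
class ExpressionMatrix:
    """Gene-by-cell expression values with identifiers and provenance.

    ``values`` is genes x cells, dense ndarray or scipy sparse.  Raw,
    filtered and selected stages must be nonnegative; the normalized
    stage is real-valued (z-scored).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        m, n = self.values.shape
        if m != len(self.gene_ids):
            raise ValueError(f"{m} rows but {len(self.gene_ids)} gene ids")
        if n != len(self.cell_ids):
            raise ValueError(f"{n} columns but {len(self.cell_ids)} cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if self.stage != Stage.NORMALIZED:
            vmin = self.values.min() if not sp.issparse(self.values) else (
                self.values.data.min() if self.values.nnz else 0.0
            )
            if vmin < 0:
                raise ValueError(f"negative entries not allowed at stage {self.stage.value}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


def _find_one(directory: Path, names: tuple[str, ...]) -> Path | None:
    for name in names:
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                return cand
    return None


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    # 10x features files carry (id, symbol, type); the first column is the id
    return df.iloc[:, 0].tolist()


def load_expression(path: str | Path, format: str) -> ExpressionMatrix:
    """Load a genes-x-cells matrix from ``mtx_dir``, ``csv`` or ``h5ad``.

    ``mtx_dir`` expects a 10x-style directory (matrix.mtx + features/genes
    + barcodes, optionally gzipped) with genes as matrix rows.  ``csv``
    (or ``.tsv``) expects gene ids in the first column and cell ids in
    the header row.  ``h5ad`` holds cells x genes and is transposed on
    load.  Sparse inputs stay sparse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")

    if format == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
            stage=Stage.RAW,
        )

    if format == "mtx_dir":
        mtx = _find_one(path, ("matrix.mtx",))
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx(.gz) in {path}")
        values = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = _find_one(path, ("features.tsv", "genes.tsv"))
        barcodes = _find_one(path, ("barcodes.tsv",))
        if genes is None or barcodes is None:
            if values.shape[0] == values.shape[1]:
                raise ValueError(
                    "square matrix without features/barcodes annotations: "
                    "orientation (genes x cells) cannot be resolved"
                )
            raise FileNotFoundError(f"missing features/barcodes annotations in {path}")
        return ExpressionMatrix(
            values=values,
            gene_ids=_read_id_column(genes),
            cell_ids=_read_id_column(barcodes),
            stage=Stage.RAW,
        )

    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        values = adata.X.T if sp.issparse(adata.X) else np.asarray(adata.X).T
        if sp.issparse(values):
            values = sp.csr_matrix(values)
        return ExpressionMatrix(
            values=values,
            gene_ids=[str(g) for g in adata.var_names],
            cell_ids=[str(c) for c in adata.obs_names],
            stage=Stage.RAW,
        )

    raise ValueError(f"unknown format {format!r}; expected mtx_dir, csv or h5ad")


def _gene_nonzero_counts(values: np.ndarray | sp.spmatrix) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=1)).ravel()
    return (values > 0).sum(axis=1)


def filter_low_genes(x: ExpressionMatrix, min_cell_fraction: float = 0.01) -> ExpressionMatrix:
    """Drop genes with nonzero expression in fewer than a fraction of cells.

    A gene is kept iff its nonzero-cell count is at least
    ``ceil(min_cell_fraction * n_cells)``; a gene expressed in exactly
    the boundary number of cells survives.
    """
    if x.stage != Stage.RAW:
        raise StageError(f"filter_low_genes expects stage raw, got {x.stage.value}")
    if not 0 < min_cell_fraction < 1:
        raise ValueError("min_cell_fraction must lie in (0, 1)")
    threshold = math.ceil(min_cell_fraction * x.n_cells)
    keep = _gene_nonzero_counts(x.values) >= threshold
    if not keep.any():
        raise ValueError(
            f"all {x.n_genes} genes removed at min_cell_fraction={min_cell_fraction}; "
            "lower the threshold"
        )
    values = x.values[keep] if not sp.issparse(x.values) else x.values[np.flatnonzero(keep)]
    return ExpressionMatrix(
        values=values,
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
        cell_ids=list(x.cell_ids),
        stage=Stage.FILTERED,
    )


def gene_variances(x: ExpressionMatrix) -> np.ndarray:
    """Per-gene population variance across cells, sparse-friendly."""
    if sp.issparse(x.values):
        v = x.values.tocsr()
        mean = np.asarray(v.mean(axis=1)).ravel()
        mean_sq = np.asarray(v.multiply(v).mean(axis=1)).ravel()
    else:
        mean = x.values.mean(axis=1)
        mean_sq = (np.asarray(x.values, dtype=float) ** 2).mean(axis=1)
    return np.maximum(mean_sq - mean**2, 0.0)


def select_top_variance_genes(x: ExpressionMatrix, n_top: int = 2000) -> ExpressionMatrix:
    """Keep the ``n_top`` genes of largest variance, ordered by descending
    variance; ties at the boundary break lexicographically on gene id."""
    if x.stage != Stage.FILTERED:
        raise StageError(f"select_top_variance_genes expects stage filtered, got {x.stage.value}")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    var = gene_variances(x)
    order = sorted(range(x.n_genes), key=lambda g: (-var[g], x.gene_ids[g]))
    order = order[: min(n_top, x.n_genes)]
    values = x.values[order] if not sp.issparse(x.values) else x.values[np.asarray(order)]
    return ExpressionMatrix(
        values=values,
        gene_ids=[x.gene_ids[g] for g in order],
        cell_ids=list(x.cell_ids),
        stage=Stage.SELECTED,
    )


def normalize(x: ExpressionMatrix, config: NormalizationConfig | None = None) -> ExpressionMatrix:
    """Normalize the selected matrix into the analysis matrix D.

    Three sub-steps, each optional through ``config``: scale each cell to
    the median library size, log(1+v), then per-gene z-score (genes with
    zero variance become all-zero rows).
    """
    if x.stage != Stage.SELECTED:
        raise StageError(f"normalize expects stage selected, got {x.stage.value}")
    config = config or NormalizationConfig()
    v = x.dense()

    if config.size_factor:
        lib = v.sum(axis=0)
        empty = lib == 0
        if empty.any():
            bad = [c for c, e in zip(x.cell_ids, empty) if e]
            raise ValueError(f"cells with zero total count: {bad}")
        v = v * (np.median(lib) / lib)[np.newaxis, :]
    if config.log1p:
        v = np.log1p(v)
    if config.zscore:
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        degenerate = (sd == 0).ravel()
        sd[sd == 0] = 1.0
        v = (v - mu) / sd
        v[degenerate, :] = 0.0
        if degenerate.any():
            log.info("%d zero-variance genes set to all-zero rows", int(degenerate.sum()))

    return ExpressionMatrix(
        values=v,
        gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids),
        stage=Stage.NORMALIZED,
    )


def preprocess(
    x: ExpressionMatrix,
    min_cell_fraction: float = 0.01,
    n_top_genes: int = 2000,
    normalization: NormalizationConfig | None = None,
) -> ExpressionMatrix:
    """Full fixed-order pipeline: filter, select, normalize."""
    return normalize(
        select_top_variance_genes(filter_low_genes(x, min_cell_fraction), n_top_genes),
        normalization,
    )


def write_csv(x: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(x.dense(), index=x.gene_ids, columns=x.cell_ids).to_csv(path)
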