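"""Construction of the composite cell-gene graph.

From the normalized expression matrix D this module builds, in order:

* B — the column-normalized bipartite relevance matrix (genes x cells),
  read as edge weights between gene and cell nodes;
* X1 — gene node features, a PCA reduction of the gene rows of B;
* X2 = Bᵀ·X1 — cell node features, each cell a relevance-weighted
  combination of the gene features;
* C — a row-normalized k-nearest-neighbour affinity over cells,
  computed from Euclidean distances in X2;
* A — the (n+m) x (n+m) block adjacency mixing the cell graph
  (weight λ) with the bipartite edges (weight 1−λ):

      A = [[λ·C,       (1−λ)·Bᵀ],
           [(1−λ)·B,   0       ]]

The gene-gene block is identically zero; λ ∈ (0, 1) trades cell-cell
against cell-gene structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .io_preprocess import ExpressionMatrix, Stage, StageError

log = logging.getLogger(__name__)


@dataclass
class BipartiteRelevance:
    """Column-normalized gene-cell relevance matrix B (m genes x n cells).

    Every column sums to 1 (or is all-zero when the cell carried no
    mass after the nonnegativity shift).
    """

    B: np.ndarray

    def __post_init__(self) -> None:
        sums = self.B.sum(axis=0)
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-9)
        if not ok.all():
            raise ValueError("columns of B must sum to 0 or 1")

    @property
    def n_genes(self) -> int:
        return self.B.shape[0]

    @property
    def n_cells(self) -> int:
        return self.B.shape[1]


@dataclass
class CellGraph:
    """Row-stochastic KNN affinity over cells (sparse n x n)."""

    C: sp.csr_matrix
    k: int


@dataclass
class BlockAdjacency:
    """Composite adjacency over n cell nodes followed by m gene nodes."""

    A: sp.csr_matrix
    n_cells: int
    n_genes: int
    lam: float

    def dense(self) -> np.ndarray:
        return np.asarray(self.A.todense(), dtype=float)


def column_normalize(d: ExpressionMatrix, mode: str = "sum") -> BipartiteRelevance:
    """Scale each cell column of D to unit sum, yielding B.

    D is z-scored and may be negative, while relevance weights must be
    nonnegative: each column is first shifted by its own minimum when
    that minimum is negative.  ``mode="l2"`` scales to unit Euclidean
    norm instead of unit sum.
    """
    if d.stage != Stage.NORMALIZED:
        raise StageError(f"column_normalize expects stage normalized, got {d.stage.value}")
    v = d.dense().copy()
    mins = v.min(axis=0)
    shift = np.where(mins < 0, -mins, 0.0)
    v = v + shift[np.newaxis, :]
    if mode == "sum":
        norms = v.sum(axis=0)
    elif mode == "l2":
        norms = np.linalg.norm(v, axis=0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    zero = norms == 0
    if zero.any():
        log.info("%d all-zero cell columns left unnormalized", int(zero.sum()))
    norms[zero] = 1.0
    return BipartiteRelevance(B=v / norms[np.newaxis, :])


def gene_features(b: BipartiteRelevance, h: int) -> np.ndarray:
    """PCA of the gene rows of B down to ``h`` dimensions (X1, m x h).

    Sign convention: in each component the loading of largest magnitude
    is made positive, so the decomposition is deterministic.
    """
    m, n = b.B.shape
    if not 1 <= h <= min(m, n):
        raise ValueError(f"h={h} must lie in [1, min(m, n)={min(m, n)}]")
    pca = PCA(n_components=h, svd_solver="full")
    scores = pca.fit_transform(b.B)
    comp = pca.components_
    flip = np.sign(comp[np.arange(h), np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip[np.newaxis, :]


def cell_features(b: BipartiteRelevance, x1: np.ndarray) -> np.ndarray:
    """X2 = Bᵀ·X1: cell features as relevance-weighted gene features."""
    if x1.shape[0] != b.n_genes:
        raise ValueError(f"X1 has {x1.shape[0]} rows but B has {b.n_genes} genes")
    return b.B.T @ x1


def knn_cell_graph(x2: np.ndarray, k: int) -> CellGraph:
    """Row-normalized KNN affinity over cells from Euclidean distances.

    Each row places uniform weight 1/(k+1) on the cell itself and its k
    nearest others; distance ties break toward the lower cell index.
    """
    n = x2.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    dist = cdist(x2, x2)
    rows, cols = [], []
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbors = [j for j in order if j != i][:k]
        rows.extend([i] * (k + 1))
        cols.extend([i] + neighbors)
    data = np.full(n * (k + 1), 1.0 / (k + 1))
    C = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return CellGraph(C=C, k=k)


def assemble_adjacency(
    c: CellGraph,
    b: BipartiteRelevance,
    lam: float,
    allow_unit: bool = False,
) -> BlockAdjacency:
    """Assemble the λ-weighted composite adjacency A (sparse).

    λ must lie strictly in (0, 1); ``allow_unit`` admits λ=1.0 for the
    cell-graph-only ablation arm of the λ sweep.
    """
    if allow_unit:
        if not 0.0 < lam <= 1.0:
            raise ValueError(f"lambda={lam} must lie in (0, 1]")
    elif not 0.0 < lam < 1.0:
        raise ValueError(f"lambda={lam} must lie strictly in (0, 1)")
    n, m = b.n_cells, b.n_genes
    if c.C.shape != (n, n):
        raise ValueError(f"cell graph is {c.C.shape} but B implies n={n}")
    Bs = sp.csr_matrix(b.B)
    A = sp.bmat(
        [
            [lam * c.C, (1.0 - lam) * Bs.T],
            [(1.0 - lam) * Bs, sp.csr_matrix((m, m))],
        ],
        format="csr",
    )
    return BlockAdjacency(A=A, n_cells=n, n_genes=m, lam=lam)


def node_features(b: BipartiteRelevance, h: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience: (X1, X2, X=[X2; X1]) with cells stacked first."""
    x1 = gene_features(b, h)
    x2 = cell_features(b, x1)
    return x1, x2, np.vstack([x2, x1])


def export_sparse(matrix: sp.spmatrix, path) -> None:
    """Write a sparse matrix as Matrix Market for external inspection."""
    import scipy.io

    scipy.io.mmwrite(str(path), sp.coo_matrix(matrix))
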