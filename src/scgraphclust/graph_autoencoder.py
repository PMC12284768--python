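"""Graph autoencoder over the composite cell-gene adjacency.

The encoder stacks graph-convolution layers

    X^(l+1) = BatchNorm(LeakyReLU(A · X^(l) · W^(l)))

taking the composite adjacency A as the (fixed, unnormalized) message
operator — self-connectivity is supplied by the KNN graph's explicit
self-loops rather than by adding an identity here.  The decoder scores
every node pair by an inner product of (optionally re-mapped)
embeddings, Â = σ(Z·Zᵀ), and training minimizes the Frobenius
reconstruction residual ‖A − Â‖_F with Adam.

After training, the first n rows of Z are the cell embeddings; K-means
on them yields the stage-one cluster assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.cluster import KMeans

from ._nn import Adam, BatchNorm, Dense, LeakyReLU
from .pathway_graph import BlockAdjacency


@dataclass
class GAEConfig:
    """Architecture and optimization settings for the autoencoder.

    layer_dims gives the output width of each graph-conv layer; the last
    entry is the embedding dimension d.  ``decoder_hidden`` toggles the
    linear + LeakyReLU re-mapping applied to Z before the inner-product
    decoder.
    """

    layer_dims: tuple[int, ...] = (256, 32)
    leaky_slope: float = 0.2
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    decoder_hidden: bool = True
    batch_norm: bool = True

    def __post_init__(self) -> None:
        self.layer_dims = tuple(int(d) for d in self.layer_dims)
        if not self.layer_dims or any(d < 1 for d in self.layer_dims):
            raise ValueError("layer_dims must be nonempty positive integers")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EmbeddingMatrix:
    """Node embeddings Z ((n+m) x d); the first n_cells rows are cells."""

    Z: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.Z).all():
            raise ValueError("embedding contains non-finite entries")

    @property
    def z_cells(self) -> np.ndarray:
        return self.Z[: self.n_cells]


@dataclass
class ClusterAssignment:
    """Integer label per cell plus per-cluster centroids in embedding space."""

    labels: np.ndarray
    centroids: np.ndarray
    K: int

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.K)):
            raise ValueError(f"labels must cover 0..{self.K - 1} with no empty cluster")


class _GraphConv:
    """One A·X·W layer with LeakyReLU and batch standardization."""

    def __init__(self, n_in: int, n_out: int, slope: float, rng: np.random.Generator,
                 batch_norm: bool = True):
        self.dense = Dense(n_in, n_out, rng, bias=False)
        self.act = LeakyReLU(slope)
        self.bn = BatchNorm(n_out) if batch_norm else None

    def forward(self, a: sp.spmatrix, x: np.ndarray) -> np.ndarray:
        self._a = a
        # A @ (X W) — identical to (A X) W but cheaper when n_out < n_in
        h = self.act.forward(a @ self.dense.forward(x))
        return self.bn.forward(h) if self.bn is not None else h

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.bn is not None:
            g = self.bn.backward(g)
        g = self.act.backward(g)
        g = self._a.T @ g
        return self.dense.backward(g)

    @property
    def params(self):
        return self.dense.params + (self.bn.params if self.bn is not None else [])

    @property
    def grads(self):
        return self.dense.grads + (self.bn.grads if self.bn is not None else [])


class GraphAutoencoder:
    """Encoder stack plus the optional decoder re-mapping layer."""

    def __init__(self, n_features: int, cfg: GAEConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        dims = [n_features, *cfg.layer_dims]
        self.convs = [
            _GraphConv(dims[i], dims[i + 1], cfg.leaky_slope, rng, cfg.batch_norm)
            for i in range(len(cfg.layer_dims))
        ]
        d = cfg.layer_dims[-1]
        if cfg.decoder_hidden:
            self.dec_dense = Dense(d, d, rng)
            self.dec_act = LeakyReLU(cfg.leaky_slope)
        else:
            self.dec_dense = None
            self.dec_act = None

    # -- forward ------------------------------------------------------
    def encode_array(self, a: sp.spmatrix, x: np.ndarray) -> np.ndarray:
        h = x
        for i, conv in enumerate(self.convs):
            h = conv.forward(a, h)
            if not np.isfinite(h).all():
                raise FloatingPointError(f"non-finite activation in graph-conv layer {i}")
        return h

    def decoder_map(self, z: np.ndarray) -> np.ndarray:
        if self.dec_dense is None:
            return z
        return self.dec_act.forward(self.dec_dense.forward(z))

    # -- backward -----------------------------------------------------
    def backward(self, g_zd: np.ndarray) -> None:
        g = g_zd
        if self.dec_dense is not None:
            g = self.dec_dense.backward(self.dec_act.backward(g))
        for conv in reversed(self.convs):
            g = conv.backward(g)

    @property
    def params(self):
        ps = [p for conv in self.convs for p in conv.params]
        if self.dec_dense is not None:
            ps += self.dec_dense.params
        return ps

    @property
    def grads(self):
        gs = [g for conv in self.convs for g in conv.grads]
        if self.dec_dense is not None:
            gs += self.dec_dense.grads
        return gs


def encode(a: BlockAdjacency, x: np.ndarray, model: GraphAutoencoder) -> EmbeddingMatrix:
    """Run the encoder on node features X = [X2; X1] (cells first)."""
    total = a.n_cells + a.n_genes
    if x.shape[0] != total:
        raise ValueError(f"X has {x.shape[0]} rows, expected n+m={total}")
    return EmbeddingMatrix(Z=model.encode_array(a.A, x), n_cells=a.n_cells)


def decode(z: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Inner-product decoder Â = σ(Z·Zᵀ); symmetric with entries in (0, 1)."""
    Z = z.Z if isinstance(z, EmbeddingMatrix) else np.asarray(z)
    return expit(Z @ Z.T)


def reconstruction_loss(a: BlockAdjacency | np.ndarray, a_hat: np.ndarray) -> float:
    """Frobenius norm of A − Â."""
    A = a.dense() if isinstance(a, BlockAdjacency) else np.asarray(a, dtype=float)
    if A.shape != a_hat.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {a_hat.shape}")
    return float(np.linalg.norm(A - a_hat))


def train_gae(
    a: BlockAdjacency,
    x: np.ndarray,
    cfg: GAEConfig,
) -> tuple[GraphAutoencoder, EmbeddingMatrix, list[float]]:
    """Fit the autoencoder by full-batch Adam on the Frobenius residual.

    Returns the trained model, the final embedding and the per-epoch
    loss trace (loss evaluated before each update, plus once after the
    final update, so the trace has ``epochs + 1`` entries).
    """
    rng = np.random.default_rng(cfg.seed)
    model = GraphAutoencoder(x.shape[1], cfg, rng)
    optimizer = Adam(model.params, lr=cfg.learning_rate)
    A_dense = a.dense()
    losses: list[float] = []

    z = None
    for epoch in range(cfg.epochs):
        z = model.encode_array(a.A, x)
        zd = model.decoder_map(z)
        a_hat = expit(zd @ zd.T)
        residual = A_dense - a_hat
        loss = float(np.linalg.norm(residual))
        if not np.isfinite(loss):
            raise FloatingPointError(f"reconstruction loss diverged at epoch {epoch}")
        losses.append(loss)
        if loss == 0.0:
            break
        g_ahat = -residual / loss
        g_m = g_ahat * a_hat * (1.0 - a_hat)
        g_zd = (g_m + g_m.T) @ zd
        model.backward(g_zd)
        optimizer.step(model.grads)

    z = model.encode_array(a.A, x)
    zd = model.decoder_map(z)
    losses.append(reconstruction_loss(A_dense, expit(zd @ zd.T)))
    return model, EmbeddingMatrix(Z=z, n_cells=a.n_cells), losses


def save_checkpoint(model: GraphAutoencoder, z: EmbeddingMatrix, path) -> None:
    """Persist trained weights and the embedding as a single .npz file."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    arrays["Z"] = z.Z
    arrays["n_cells"] = np.array(z.n_cells)
    np.savez(path, **arrays)


def load_checkpoint(model: GraphAutoencoder, path) -> EmbeddingMatrix:
    """Restore weights in place into a model of identical architecture."""
    data = np.load(path)
    params = model.params
    for i, p in enumerate(params):
        saved = data[f"param_{i}"]
        if saved.shape != p.shape:
            raise ValueError(f"checkpoint parameter {i} has shape {saved.shape}, expected {p.shape}")
        p[...] = saved
    return EmbeddingMatrix(Z=data["Z"], n_cells=int(data["n_cells"]))


def initial_clusters(z_cells: np.ndarray, K: int, seed: int) -> ClusterAssignment:
    """Stage-one labels: K-means on cell embeddings, 10 restarts, seeded.

    Centroids are recomputed as exact member means of the returned
    partition.
    """
    n = z_cells.shape[0]
    if not 2 <= K <= n:
        raise ValueError(f"K={K} must satisfy 2 <= K <= n={n}")
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(z_cells)
    centroids = np.vstack([z_cells[labels == c].mean(axis=0) for c in range(K)])
    return ClusterAssignment(labels=labels, centroids=centroids, K=K)
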