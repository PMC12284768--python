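import dataclasses

import numpy as np
import pytest

from scgraphclust import (
    GAEConfig,
    GANConfig,
    PipelineConfig,
    SynthConfig,
    assemble_adjacency,
    column_normalize,
    knn_cell_graph,
    preprocess,
    simulate_counts,
)
from scgraphclust.pathway_graph import node_features
from scgraphclust.pipeline import GraphConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_synth_config(**overrides) -> SynthConfig:
    """A fast, strongly separated three-population dataset for unit tests."""
    base = dict(
        n_cells=90,
        n_genes=60,
        K=3,
        marker_genes_per_cluster=10,
        fold_change=8.0,
        dropout_rate=0.2,
        seed=7,
    )
    base.update(overrides)
    return SynthConfig(**base)


def small_pipeline_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Reduced architecture/epochs so full-pipeline tests stay fast."""
    cfg = PipelineConfig(
        graph=GraphConfig(h=20, k=8, lam=0.3),
        gae=GAEConfig(layer_dims=(64, 16), epochs=60, seed=seed),
        K=3,
        gan=GANConfig(epochs=25, seed=seed + 1),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@pytest.fixture
def small_counts():
    return simulate_counts(small_synth_config())


@pytest.fixture
def small_graph(small_counts):
    """(adjacency, node features, truth labels) for a small planted dataset."""
    x, labels = small_counts
    d = preprocess(x)
    b = column_normalize(d)
    x1, x2, feats = node_features(b, 20)
    c = knn_cell_graph(x2, 8)
    a = assemble_adjacency(c, b, 0.3)
    return a, feats, labels
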