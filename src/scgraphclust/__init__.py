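"""Two-stage single-cell clustering over a composite cell-gene graph.

Stage one embeds cells and genes jointly with a graph autoencoder over
a λ-weighted block adjacency (cell-cell KNN graph plus cell-gene
relevance edges) and clusters the cell embeddings with K-means.  Stage
two trains an auxiliary-classifier GAN on the centroid-proximal
high-confidence cells and re-labels every cell with the discriminator's
class head.
"""

from .adversarial_refine import (
    GANConfig,
    RefinedAssignment,
    discriminator_loss,
    generator_loss,
    relabel_all,
    train_gan,
)
from .confidence import (
    ConfidenceSet,
    centroid_distances,
    confidence_frame,
    select_high_confidence,
)
from .graph_autoencoder import (
    ClusterAssignment,
    EmbeddingMatrix,
    GAEConfig,
    decode,
    encode,
    initial_clusters,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
    train_gae,
)
from .io_preprocess import (
    ExpressionMatrix,
    NormalizationConfig,
    Stage,
    filter_low_genes,
    load_expression,
    normalize,
    preprocess,
    select_top_variance_genes,
)
from .metrics import (
    adjusted_rand_index,
    clustering_accuracy,
    evaluate_all,
    fowlkes_mallows_index,
    normalized_mutual_information,
)
from .pathway_graph import (
    BipartiteRelevance,
    BlockAdjacency,
    CellGraph,
    assemble_adjacency,
    cell_features,
    column_normalize,
    gene_features,
    knn_cell_graph,
)
from .pipeline import PipelineConfig, PipelineResult, gan_ablation, lambda_sweep, run_pipeline
from .synth import SynthConfig, simulate_counts

__version__ = "0.1.0"

__all__ = [
    "ExpressionMatrix", "NormalizationConfig", "Stage",
    "load_expression", "filter_low_genes", "select_top_variance_genes",
    "normalize", "preprocess",
    "BipartiteRelevance", "CellGraph", "BlockAdjacency",
    "column_normalize", "gene_features", "cell_features",
    "knn_cell_graph", "assemble_adjacency",
    "GAEConfig", "EmbeddingMatrix", "ClusterAssignment",
    "encode", "decode", "reconstruction_loss", "train_gae", "initial_clusters",
    "save_checkpoint", "load_checkpoint",
    "ConfidenceSet", "centroid_distances", "select_high_confidence", "confidence_frame",
    "GANConfig", "RefinedAssignment",
    "discriminator_loss", "generator_loss", "train_gan", "relabel_all",
    "adjusted_rand_index", "clustering_accuracy",
    "normalized_mutual_information", "fowlkes_mallows_index", "evaluate_all",
    "SynthConfig", "simulate_counts",
    "PipelineConfig", "PipelineResult", "run_pipeline", "lambda_sweep", "gan_ablation",
]
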