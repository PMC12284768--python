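# scgraphclust

Two-stage clustering of single-cell RNA-seq data over a composite
cell-gene graph: a graph autoencoder embeds cells and genes jointly,
K-means produces initial clusters, and an auxiliary-classifier GAN
trained on the most centroid-proximal ("high-confidence") cells
re-labels every cell.

## Who this is for

Computational biologists clustering scRNA-seq count matrices who want
cell-gene interactions — not only cell-cell similarity — to shape the
embedding, plus an adversarial second stage that cleans up boundary
assignments using the most reliable cells of each cluster as labeled
training data.

## Method

Given a gene-by-cell count matrix, preprocessing removes genes with
nonzero expression in fewer than 1% of cells, keeps the 2000 most
variable genes, and normalizes (median-library-size scaling, log1p,
per-gene z-score) to a matrix **D**.

**Stage 1 — graph embedding.** Column-normalizing D gives a bipartite
relevance matrix **B** (m genes × n cells) read as cell↔gene edge
weights. Gene features X1 are a PCA reduction of the gene rows of B;
cell features follow as X2 = Bᵀ·X1. A row-stochastic KNN graph **C**
over cells (Euclidean distances in X2) and B are combined into the
(n+m)×(n+m) block adjacency

```
A = [ λ·C        (1−λ)·Bᵀ ]
    [ (1−λ)·B    0        ]        λ ∈ (0, 1), default 0.3
```

A graph autoencoder with layers
`X⁽ˡ⁺¹⁾ = BatchNorm(LeakyReLU(A·X⁽ˡ⁾·W⁽ˡ⁾))` encodes the node
features X = [X2; X1] into embeddings Z; the decoder reconstructs
Â = σ(Z·Zᵀ) and training minimizes the Frobenius residual ‖A − Â‖_F.
K-means on the first n rows of Z (the cells) yields stage-1 labels.

**Stage 2 — adversarial refinement.** Per cluster, the 30% of cells
closest to their centroid are kept as labeled training data. A
conditional generator ([x‖z] → 1024 → 512 → 256 → d, LeakyReLU 0.2,
tanh output) and a discriminator with a real/fake head and a K-way
class head are trained adversarially (Adam, learning rate halved every
five epochs); the discriminator's class head then re-labels every cell
by argmax class probability.

Agreement with reference labels is scored by ARI, best-mapping ACC,
NMI and FMI, implemented from contingency-table definitions.

## Worked example

Simulate a 3-population dataset and cluster it:

```bash
scgraphclust simulate --outdir demo/data --n-cells 600 --n-genes 300 --k 3 --seed 1
scgraphclust run demo/data --k 3 --seed 1 \
    --truth demo/data/truth_labels.csv --outdir demo/run
```

which prints

```json
{
  "initial": {"ari": 1.0, "acc": 1.0, "nmi": 1.0, "fmi": 1.0},
  "refined": {"ari": 1.0, "acc": 1.0, "nmi": 1.0, "fmi": 1.0}
}
```

— at this separation (8-fold marker up-regulation) both the K-means
stage and the adversarial stage recover the planted populations
exactly. `demo/run/labels.csv` holds per-cell labels from both stages
with the class-head confidence:

```
cell_id,initial_label,refined_label,max_class_probability
cell_00000,0,0,0.9847400361392387
cell_00001,2,2,0.9944985827897598
...
```

The λ-sweep and GAN-ablation experiments are available as
`scgraphclust sweep-lambda` and `scgraphclust ablate-gan`; the same
functionality is importable (`scgraphclust.run_pipeline`,
`lambda_sweep`, `gan_ablation`).

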