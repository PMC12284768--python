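"""High-confidence cell selection for adversarial refinement.

Cells nearest their own cluster centroid in embedding space are the
most reliable carriers of the stage-one labels; the closest fraction
(recommended 30%-50%) of each cluster is kept as labeled training data
for the GAN, with at least one cell per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_autoencoder import ClusterAssignment


@dataclass
class ConfidenceSet:
    """Selected centroid-proximal cells with their stage-one labels."""

    indices: np.ndarray
    x_real: np.ndarray
    y_real: np.ndarray
    fraction: float


def centroid_distances(z_cells: np.ndarray, assign: ClusterAssignment) -> np.ndarray:
    """Euclidean distance of every cell to its own cluster centroid."""
    if z_cells.shape[0] != assign.labels.shape[0]:
        raise ValueError("assignment length does not match embedding rows")
    for c in range(assign.K):
        if not (assign.labels == c).any():
            raise ValueError(f"cluster {c} is empty")
    diffs = z_cells - assign.centroids[assign.labels]
    return np.linalg.norm(diffs, axis=1)


def select_high_confidence(
    z_cells: np.ndarray,
    assign: ClusterAssignment,
    fraction: float = 0.3,
) -> ConfidenceSet:
    """Keep, per cluster, the closest ``max(1, round(fraction * size))``
    cells to the centroid (round-half-up; distance ties break toward the
    lower cell index)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction={fraction} must lie in (0, 1]")
    dist = centroid_distances(z_cells, assign)
    selected: list[int] = []
    for c in range(assign.K):
        members = np.flatnonzero(assign.labels == c)
        keep = max(1, math.floor(fraction * members.size + 0.5))
        order = members[np.lexsort((members, dist[members]))]
        selected.extend(order[:keep].tolist())
    indices = np.array(sorted(selected), dtype=int)
    return ConfidenceSet(
        indices=indices,
        x_real=z_cells[indices],
        y_real=assign.labels[indices].astype(int),
        fraction=fraction,
    )


def confidence_frame(
    z_cells: np.ndarray,
    assign: ClusterAssignment,
    conf: ConfidenceSet,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell selection table (cell_id, cluster, distance, selected)."""
    n = z_cells.shape[0]
    dist = centroid_distances(z_cells, assign)
    selected = np.zeros(n, dtype=bool)
    selected[conf.indices] = True
    return pd.DataFrame(
        {
            "cell_id": cell_ids if cell_ids is not None else [str(i) for i in range(n)],
            "cluster": assign.labels,
            "distance": dist,
            "selected": selected,
        }
    )
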