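"""External clustering-agreement metrics: ARI, ACC, NMI, FMI.

All four are computed from the truth-vs-predicted contingency table.
ACC uses an optimal one-to-one label mapping (rectangular assignment,
so differing cluster counts are handled); the NMI normalizer is
configurable with the arithmetic mean of entropies as default.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)


def _validate(truth, predicted, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, got {t.shape} vs {p.shape}")
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} items")
    if t.size and (t.min() < 0 or p.min() < 0):
        raise ValueError("labels must be nonnegative")
    return t, p


def contingency_table(truth, predicted) -> np.ndarray:
    """Counts n_ij of items with truth label i and predicted label j."""
    t, p = _validate(truth, predicted)
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(truth, predicted) -> float:
    """Pair-counting Rand index adjusted for chance; 1 iff identical
    partitions, ~0 for independent ones."""
    t, p = _validate(truth, predicted, min_n=2)
    table = contingency_table(t, p)
    n = t.size
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    total = _comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial (all-one-block or all-singletons)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def clustering_accuracy(truth, predicted) -> float:
    """Fraction of agreeing items under the best one-to-one label mapping."""
    t, p = _validate(truth, predicted, min_n=1)
    table = contingency_table(t, p)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / t.size)


def _entropy(counts: np.ndarray, n: int) -> float:
    pk = counts[counts > 0] / n
    return float(-(pk * np.log(pk)).sum())


def normalized_mutual_information(truth, predicted, normalizer: str = "arithmetic") -> float:
    """Mutual information normalized by a mean of the two label entropies.

    ``normalizer`` is one of min / geometric / arithmetic / max.  Two
    identical trivial partitions score 1; if the normalizer is zero
    otherwise the score is 0.
    """
    t, p = _validate(truth, predicted, min_n=2)
    table = contingency_table(t, p)
    n = t.size
    h_t = _entropy(table.sum(axis=1), n)
    h_p = _entropy(table.sum(axis=0), n)
    nz = table[table > 0].astype(float)
    outer = np.outer(table.sum(axis=1), table.sum(axis=0))[table > 0].astype(float)
    mi = float((nz / n * (np.log(n * nz) - np.log(outer))).sum())
    if h_t == 0.0 and h_p == 0.0:
        return 1.0
    norms = {
        "min": min(h_t, h_p),
        "geometric": np.sqrt(h_t * h_p),
        "arithmetic": 0.5 * (h_t + h_p),
        "max": max(h_t, h_p),
    }
    if normalizer not in norms:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    denom = norms[normalizer]
    if denom == 0.0:
        return 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def fowlkes_mallows_index(truth, predicted) -> float:
    """TP / sqrt((TP+FP)(TP+FN)) over same-cluster item pairs."""
    t, p = _validate(truth, predicted, min_n=2)
    table = contingency_table(t, p)
    tp = _comb2(table).sum()
    pairs_t = _comb2(table.sum(axis=1)).sum()
    pairs_p = _comb2(table.sum(axis=0)).sum()
    if pairs_t == 0 or pairs_p == 0:
        log.info("degenerate partition with no same-cluster pairs; FMI defined 0")
        return 0.0
    return float(tp / np.sqrt(pairs_t * pairs_p))


def evaluate_all(truth, predicted, nmi_normalizer: str = "arithmetic") -> dict[str, float]:
    """All four metrics as a dict (keys ari, acc, nmi, fmi)."""
    return {
        "ari": adjusted_rand_index(truth, predicted),
        "acc": clustering_accuracy(truth, predicted),
        "nmi": normalized_mutual_information(truth, predicted, nmi_normalizer),
        "fmi": fowlkes_mallows_index(truth, predicted),
    }
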