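"""External and internal clustering validation metrics.

External (need a reference partition): adjusted Rand index, normalized
mutual information (geometric-mean normalization, natural logs), Jaccard
index over object pairs, and the correct selection rate of the estimated
number of clusters.  Internal (need the data): silhouette index and the
Calinski-Harabasz variance-ratio index, both under Euclidean distance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .core import DataMatrix, validate_labels

__all__ = [
    "pair_counts",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "jaccard_index",
    "silhouette",
    "calinski_harabasz",
    "correct_selection_rate",
]


def _contingency(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    tu, ti = np.unique(truth, return_inverse=True)
    pu, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((tu.size, pu.size), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def pair_counts(truth, pred) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) over the C(n,2) object pairs: co-clustered in both /
    predicted only / truth only / neither."""
    table = _contingency(truth, pred)
    n = int(table.sum())
    total = n * (n - 1) // 2

    def _c2(x):
        return int(np.sum(x.astype(np.int64) * (x - 1) // 2))

    tp = _c2(table.ravel())
    same_pred = _c2(table.sum(axis=0))
    same_truth = _c2(table.sum(axis=1))
    fp = same_pred - tp
    fn = same_truth - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def adjusted_rand_index(truth, pred) -> float:
    """Hubert-Arabie chance-adjusted Rand index."""
    table = _contingency(truth, pred)
    n = int(table.sum())
    sum_cells = np.sum(table.astype(np.int64) * (table - 1) // 2)
    a = table.sum(axis=1).astype(np.int64)
    b = table.sum(axis=0).astype(np.int64)
    sum_a = np.sum(a * (a - 1) // 2)
    sum_b = np.sum(b * (b - 1) // 2)
    total = n * (n - 1) // 2
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def normalized_mutual_information(truth, pred) -> float:
    """I(U;V) / sqrt(H(U) H(V)), natural logs.

    Zero-entropy conventions: 1 when both partitions are the identical
    single-cluster partition, otherwise 0 when either entropy vanishes.
    """
    table = _contingency(truth, pred).astype(float)
    n = table.sum()
    p = table / n
    pu = p.sum(axis=1)
    pv = p.sum(axis=0)

    def _entropy(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    hu, hv = _entropy(pu), _entropy(pv)
    if hu == 0.0 or hv == 0.0:
        same = table.shape == (1, 1)
        return 1.0 if same else 0.0
    nz = p > 0
    mi = float(np.sum(p[nz] * (np.log(p[nz])
                               - np.log(np.outer(pu, pv))[nz])))
    return float(np.clip(mi / np.sqrt(hu * hv), 0.0, 1.0))


def jaccard_index(truth, pred) -> float:
    """TP / (TP + FP + FN) over pairs; 0/0 counts as 1 (all-singleton case)."""
    tp, fp, fn, _ = pair_counts(truth, pred)
    denom = tp + fp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def silhouette(m: DataMatrix, labels) -> float:
    """Mean silhouette width under Euclidean distance; singletons score 0."""
    labels = validate_labels(labels, m.n)
    k = int(labels.max())
    if k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if m.n < 3:
        raise ValueError("silhouette needs at least 3 objects")
    dist = cdist(m.values, m.values)
    scores = np.zeros(m.n)
    members = [np.flatnonzero(labels == c + 1) for c in range(k)]
    sizes = np.array([mm.size for mm in members])
    for i in range(m.n):
        c = labels[i] - 1
        if sizes[c] == 1:
            continue  # singleton convention: 0
        a = dist[i, members[c]].sum() / (sizes[c] - 1)
        b = min(
            dist[i, members[o]].mean() for o in range(k) if o != c
        )
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def calinski_harabasz(m: DataMatrix, labels) -> float:
    """Variance-ratio index: [B/(K-1)] / [W/(n-K)]; +inf when W = 0."""
    labels = validate_labels(labels, m.n)
    k = int(labels.max())
    n = m.n
    if k < 2 or n <= k:
        raise ValueError("Calinski-Harabasz needs 2 <= K < n")
    grand = m.values.mean(axis=0)
    between = within = 0.0
    for c in range(k):
        x = m.values[labels == c + 1]
        cent = x.mean(axis=0)
        between += x.shape[0] * float(np.sum((cent - grand) ** 2))
        within += float(np.sum((x - cent) ** 2))
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def correct_selection_rate(k_hats, k_true: int) -> float:
    """Fraction of runs whose selected number of clusters equals the truth."""
    k_hats = list(k_hats)
    if not k_hats:
        raise ValueError("empty list of selected cluster counts")
    return sum(1 for k in k_hats if k == k_true) / len(k_hats)
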