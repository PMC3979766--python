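"""Pairwise cluster cohesion and the max-vs-median merging rule.

Each cluster is modelled as a multivariate normal fitted to its members.
The cohesion of clusters i and j is the average, over the union of their
members, of a per-object similarity built from the two fitted densities:

    s_ij(x) = 2 * min(p_i(x), p_j(x)) / (p_i(x) + p_j(x))

which is symmetric, lies in (0, 1], equals 1 when the densities coincide
and vanishes for disjoint supports.  A merge pass repeatedly merges the
pair with the largest cohesion while that maximum is at least ``gamma``
times the median of all pairwise cohesions; with fewer than three pairs
the median is not robust and no merge occurs.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .core import (
    CovStructure,
    DataMatrix,
    GaussianComponent,
    estimate_covariance,
    logpdf_rows,
    validate_labels,
)

__all__ = [
    "fit_cluster_gaussian",
    "cohesion",
    "cohesion_matrix",
    "merge_pass",
    "absorb_small_clusters",
]

logger = logging.getLogger(__name__)

#: Floor on the per-object density ratio, in log space, so cohesion never
#: returns exactly zero.
_MIN_RATIO = 1e-300

#: Minimum cohesion for a pair to be considered mergeable at all.  The
#: max-vs-median ratio test is meaningless when every pairwise cohesion has
#: underflown to the floor: the ratio of two negligible numbers says
#: nothing about closeness.  Pairs of clusters that genuinely overlap score
#: orders of magnitude above this (well-separated unit-variance clusters a
#: hundred sds apart already score below 1e-6).
MERGEABLE_FLOOR = 1e-6


def fit_cluster_gaussian(
    m: DataMatrix, members, cov: CovStructure = CovStructure.FULL
) -> GaussianComponent:
    """Fit a Gaussian to a cluster's member rows (centroid + structured,
    regularized covariance); weight is the member fraction of the dataset."""
    members = np.asarray(list(members), dtype=int)
    if members.size < 2:
        raise ValueError("cannot fit a Gaussian to fewer than 2 members")
    x = m.values[members]
    mean = x.mean(axis=0)
    covariance = estimate_covariance(x, mean, cov)
    return GaussianComponent(members.size / m.n, mean, covariance)


def cohesion(
    ci: GaussianComponent,
    cj: GaussianComponent,
    members_i,
    members_j,
    m: DataMatrix,
) -> float:
    """Normalized-min-density similarity of two fitted clusters, in (0, 1]."""
    members_i = np.asarray(list(members_i), dtype=int)
    members_j = np.asarray(list(members_j), dtype=int)
    union = np.concatenate([members_i, members_j])
    x = m.values[union]
    lp_i = logpdf_rows(x, ci.mean, ci.covariance)
    lp_j = logpdf_rows(x, cj.mean, cj.covariance)
    # s = 2 min(p_i, p_j) / (p_i + p_j) = 2 / (1 + exp(|log p_i - log p_j|)),
    # evaluated stably in log space.
    gap = np.abs(lp_i - lp_j)
    s = 2.0 / (1.0 + np.exp(np.minimum(gap, 700.0)))
    s = np.maximum(s, _MIN_RATIO)
    return float(np.mean(s))


def _cluster_members(labels: np.ndarray) -> list[np.ndarray]:
    k = int(labels.max())
    return [np.flatnonzero(labels == c + 1) for c in range(k)]


def _absorb_singletons(
    labels: np.ndarray, m: DataMatrix, min_members: int = 2
) -> np.ndarray:
    """Fold clusters smaller than ``min_members`` into the nearest-centroid
    cluster (Gaussian fits need at least two members; callers may demand a
    larger coding-validity floor)."""
    min_members = max(2, int(min_members))
    labels = labels.copy()
    while int(labels.max()) > 1:
        members = _cluster_members(labels)
        sizes = np.array([mm.size for mm in members])
        if np.all(sizes >= min_members) or (sizes >= min_members).sum() == 0:
            break
        lone = int(np.argmin(sizes))
        point = m.values[members[lone][0]]
        cents = [m.values[mm].mean(axis=0) if c != lone else None
                 for c, mm in enumerate(members)]
        dists = [np.inf if c is None else float(np.linalg.norm(point - c))
                 for c in cents]
        target = int(np.argmin(dists))
        logger.info("absorbing undersized cluster %d into cluster %d",
                    lone + 1, target + 1)
        labels[labels == lone + 1] = target + 1
        labels = _compact(labels)
    return labels


def absorb_small_clusters(
    labels: np.ndarray, m: DataMatrix, min_members: int = 2
) -> np.ndarray:
    """Public wrapper: fold clusters below ``min_members`` into their
    nearest-centroid neighbour and re-compact the labels."""
    return _absorb_singletons(
        validate_labels(labels, m.n), m, min_members=min_members
    )


def _compact(labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    remap = {int(old): new + 1 for new, old in enumerate(uniq)}
    return np.array([remap[int(v)] for v in labels], dtype=int)


def cohesion_matrix(
    labels: np.ndarray, m: DataMatrix, cov: CovStructure
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """K x K symmetric cohesion matrix (unit diagonal) plus the pair list."""
    labels = validate_labels(labels, m.n)
    members = _cluster_members(labels)
    comps = [fit_cluster_gaussian(m, mm, cov) for mm in members]
    k = len(members)
    mat = np.eye(k)
    pairs: list[tuple[int, int, float]] = []
    for i, j in combinations(range(k), 2):
        c = cohesion(comps[i], comps[j], members[i], members[j], m)
        mat[i, j] = mat[j, i] = c
        pairs.append((i, j, c))
    return mat, pairs


def merge_pass(
    labels: np.ndarray,
    m: DataMatrix,
    gamma: float = 20.0,
    cov: CovStructure = CovStructure.FULL,
) -> tuple[np.ndarray, int]:
    """Merge clusters while max cohesion >= gamma * median cohesion.

    Returns the final (contiguous) labels and the number of merges.  With
    fewer than three pairwise cohesions the median test is skipped and no
    merge occurs; K < 2 returns the input unchanged.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    labels = validate_labels(labels, m.n)
    if labels.max() < 2:
        return labels, 0
    labels = _absorb_singletons(labels, m)
    merge_count = 0
    while labels.max() >= 2:
        _, pairs = cohesion_matrix(labels, m, cov)
        if len(pairs) < 3:
            break
        vals = np.array([c for _, _, c in pairs])
        med = float(np.median(vals))
        top = int(np.argmax(vals))
        if vals[top] < MERGEABLE_FLOOR or vals[top] < gamma * med:
            break
        i, j, _ = pairs[top]
        labels[labels == j + 1] = i + 1
        labels = _compact(labels)
        merge_count += 1
    return labels, merge_count
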