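"""One-prototype-take-one-cluster (OPTOC) competitive learning.

Each prototype P carries two auxiliary vectors: the asymptotic property
vector (APV, A) defines a shrinking dynamic neighbourhood that guides the
prototype into a single natural cluster, and the distant property vector
(DPV, D) tracks patterns far from the prototype and seeds new prototypes
when a cluster is split.  An input X with winner prototype i is "inside"
the neighbourhood when ||X - P_i|| <= ||A_i - P_i||; inside patterns pull
both P and A, outside patterns only push the DPV outward.  The prototype
learning rate is alpha = (||A-P|| / (||X-P|| + ||A-P||))^2, so patterns
outside the neighbourhood contribute less.

Convergence is judged by the relative quantity ||A - P|| / data_scale,
where data_scale is the dataset radius, making the threshold eps a
data-independent number (default 0.005).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import DataMatrix, validate_labels

__all__ = [
    "OptocState",
    "init_learner",
    "optoc_epoch",
    "has_converged",
    "split_largest_variance",
    "assign_nearest",
]

logger = logging.getLogger(__name__)

#: Hard cap on learning epochs in one phase; prevents non-termination on
#: pathological data (a warning is logged if the cap is hit).
MAX_EPOCHS = 500


@dataclass
class OptocState:
    """Prototypes with paired APV/DPV vectors and learning counters."""

    prototypes: list[np.ndarray]
    apv: list[np.ndarray]
    dpv: list[np.ndarray]
    apv_count: list[int]
    dpv_count: list[int]
    data_scale: float

    def __post_init__(self) -> None:
        k = len(self.prototypes)
        if k < 1:
            raise ValueError("need at least one prototype")
        if not (len(self.apv) == len(self.dpv) == len(self.apv_count)
                == len(self.dpv_count) == k):
            raise ValueError("prototype/APV/DPV/counter lists must align")
        if self.data_scale <= 0:
            raise ValueError("data_scale must be positive")

    @property
    def k(self) -> int:
        return len(self.prototypes)

    def copy(self) -> "OptocState":
        return OptocState(
            [p.copy() for p in self.prototypes],
            [a.copy() for a in self.apv],
            [d.copy() for d in self.dpv],
            list(self.apv_count),
            list(self.dpv_count),
            self.data_scale,
        )


def _dataset_scale(values: np.ndarray) -> float:
    center = values.mean(axis=0)
    radius = float(np.max(np.linalg.norm(values - center, axis=1)))
    return radius if radius > 0 else 1.0


def init_learner(m: DataMatrix, rng: np.random.Generator) -> OptocState:
    """Start with one prototype at a random data row.

    The APV is placed at the object farthest from the prototype (the
    necessary far-initialization of the OPTOC mechanism) and the DPV at the
    prototype itself; counters start at zero.
    """
    if m.n < 2:
        raise ValueError("need at least 2 objects")
    x = m.values
    p = x[int(rng.integers(m.n))].copy()
    far = int(np.argmax(np.linalg.norm(x - p, axis=1)))
    return OptocState(
        prototypes=[p],
        apv=[x[far].copy()],
        dpv=[p.copy()],
        apv_count=[0],
        dpv_count=[0],
        data_scale=_dataset_scale(x),
    )


def optoc_epoch(s: OptocState, m: DataMatrix, rng: np.random.Generator) -> OptocState:
    """One full online pass over the rows in a freshly randomized order."""
    s = s.copy()
    order = rng.permutation(m.n)
    protos = np.stack(s.prototypes)
    for idx in order:
        x = m.values[idx]
        dists = np.linalg.norm(protos - x, axis=1)
        i = int(np.argmin(dists))
        p = protos[i]
        dx = float(dists[i])
        da = float(np.linalg.norm(s.apv[i] - p))
        if dx <= da:
            # inside the dynamic neighbourhood: pull APV and prototype
            s.apv_count[i] += 1
            s.apv[i] = s.apv[i] + (x - s.apv[i]) / s.apv_count[i]
            denom = dx + da
            alpha = (da / denom) ** 2 if denom > 0 else 1.0
            protos[i] = p + alpha * (x - p)
        else:
            denom = dx + da
            alpha = (da / denom) ** 2 if denom > 0 else 0.0
            protos[i] = p + alpha * (x - p)
            # outside and farther than the current DPV: push the DPV out
            if dx >= float(np.linalg.norm(s.dpv[i] - p)):
                s.dpv_count[i] += 1
                s.dpv[i] = s.dpv[i] + (x - s.dpv[i]) / s.dpv_count[i]
    s.prototypes = [protos[j].copy() for j in range(s.k)]
    return s


def has_converged(s: OptocState, eps: float) -> bool:
    """True iff every prototype's APV is within ``eps`` of it, relative to
    the dataset radius."""
    if not (0.0 < eps < 1.0):
        raise ValueError("eps must lie in (0, 1)")
    for p, a in zip(s.prototypes, s.apv):
        if np.linalg.norm(a - p) / s.data_scale > eps:
            return False
    return True


def learn_until_converged(
    s: OptocState,
    m: DataMatrix,
    rng: np.random.Generator,
    eps: float = 0.005,
    max_epochs: int = MAX_EPOCHS,
) -> OptocState:
    """Run epochs until the relative convergence test passes (or the cap)."""
    for _ in range(max_epochs):
        if has_converged(s, eps):
            return s
        s = optoc_epoch(s, m, rng)
    if not has_converged(s, eps):
        logger.warning(
            "OPTOC learning stopped after %d epochs without convergence",
            max_epochs,
        )
    return s


def _assign_raw(m: DataMatrix, s: OptocState) -> np.ndarray:
    protos = np.stack(s.prototypes)
    d2 = ((m.values[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # first minimum wins: low index breaks ties


def assign_nearest(m: DataMatrix, s: OptocState) -> np.ndarray:
    """Label each row by its nearest prototype; compact to contiguous 1..K.

    Ties break toward the lower prototype index; prototypes owning no rows
    are dropped from the labelling.
    """
    raw = _assign_raw(m, s)
    used = np.unique(raw)
    remap = {int(old): new + 1 for new, old in enumerate(used)}
    return np.array([remap[int(r)] for r in raw], dtype=int)


def prune_empty(s: OptocState, m: DataMatrix) -> tuple[OptocState, np.ndarray]:
    """Drop prototypes owning no rows; return the pruned state and labels
    aligned with its prototype order."""
    raw = _assign_raw(m, s)
    used = [int(u) for u in np.unique(raw)]
    out = OptocState(
        [s.prototypes[j].copy() for j in used],
        [s.apv[j].copy() for j in used],
        [s.dpv[j].copy() for j in used],
        [s.apv_count[j] for j in used],
        [s.dpv_count[j] for j in used],
        s.data_scale,
    )
    remap = {old: new + 1 for new, old in enumerate(used)}
    labels = np.array([remap[int(r)] for r in raw], dtype=int)
    return out, labels


def split_largest_variance(
    s: OptocState, m: DataMatrix, labels: np.ndarray
) -> OptocState:
    """Split the cluster with the largest mean squared member-to-prototype
    distance by appending a prototype seeded at that cluster's DPV.

    All existing prototypes keep their positions but their APVs are reset to
    their farthest member (counters to zero) so every unit re-learns after
    the split.  Clusters with fewer than two members are ineligible.
    """
    labels = validate_labels(labels, m.n)
    k = int(labels.max())
    if k != s.k:
        raise ValueError(
            f"labels have {k} clusters but state has {s.k} prototypes; "
            "labels must be the nearest-prototype assignment"
        )
    x = m.values
    best_c, best_msd = -1, -np.inf
    for c in range(k):
        members = np.flatnonzero(labels == c + 1)
        if members.size < 2:
            continue
        msd = float(np.mean(np.sum((x[members] - s.prototypes[c]) ** 2, axis=1)))
        if msd > best_msd:
            best_c, best_msd = c, msd
    if best_c < 0:
        raise ValueError("nothing to split: no cluster has at least 2 members")

    members = np.flatnonzero(labels == best_c + 1)
    if s.dpv_count[best_c] > 0:
        new_p = s.dpv[best_c].copy()
    else:
        far = members[np.argmax(
            np.linalg.norm(x[members] - s.prototypes[best_c], axis=1))]
        new_p = x[far].copy()
    new_apv_idx = members[np.argmax(np.linalg.norm(x[members] - new_p, axis=1))]

    out = s.copy()
    for c in range(k):
        own = np.flatnonzero(labels == c + 1)
        far = own[np.argmax(np.linalg.norm(x[own] - out.prototypes[c], axis=1))]
        out.apv[c] = x[far].copy()
        out.dpv[c] = out.prototypes[c].copy()
        out.apv_count[c] = 0
        out.dpv_count[c] = 0
    out.prototypes.append(new_p)
    out.apv.append(x[new_apv_idx].copy())
    out.dpv.append(new_p.copy())
    out.apv_count.append(0)
    out.dpv_count.append(0)
    return out
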