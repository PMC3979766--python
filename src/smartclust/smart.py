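"""Splitting-while-merging orchestrators.

Both algorithms interleave cluster splitting with merge checks in a single
loop, record a candidate clustering after every learn-and-merge phase and
stop once the cumulative number of merges reaches ``m_max``; the candidate
with the minimal message length is returned.

* The competitive-learning variant (``run_smart1``) learns prototypes with
  OPTOC, merges via the cohesion max-vs-median rule, and splits the cluster
  with the largest within-cluster variance.
* The mixture-model variant (``run_smart2``) runs modified component-wise
  EM, in which merges are weight annihilations, and splits by injecting a
  deterministic new component at the farthest data row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cem2 import (
    _MIN_QUANT_MASS,
    AllComponentsAnnihilated,
    cem2_run,
    hard_labels,
    split_inject,
)
from .cohesion import absorb_small_clusters, merge_pass
from .core import (
    CovStructure,
    DataMatrix,
    GaussianComponent,
    MixtureModel,
    estimate_covariance,
    logpdf_rows,
    regularize_covariance,
)
from .mml import (
    ClusteringCandidate,
    message_length,
    n_params_per_component,
    partition_to_mixture,
    select_best,
)
from .optoc import (
    OptocState,
    init_learner,
    learn_until_converged,
    prune_empty,
    split_largest_variance,
)

__all__ = ["SmartConfig", "SmartResult", "run_smart1", "run_smart2", "run"]

logger = logging.getLogger(__name__)


def default_cov_structure(d: int) -> CovStructure:
    """Full covariance for low-dimensional demonstrations, diagonal for
    gene-expression dimensionality (keeps N/2 below realistic cluster sizes)."""
    return CovStructure.FULL if d <= 3 else CovStructure.DIAGONAL


@dataclass
class SmartConfig:
    """Shared configuration for both orchestrators.

    eps     OPTOC relative convergence threshold (data-independent).
    gamma   cohesion max-vs-median merge ratio.
    m_max   cumulative merges before the loop terminates.
    """

    method: str = "smart2"
    eps: float = 0.005
    gamma: float = 20.0
    m_max: int = 5
    cov_structure: CovStructure | None = None  # None -> full if d<=3 else diagonal
    tol: float = 1e-5
    max_sweeps: int = 500
    max_epochs: int = 500
    hold_sweeps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("smart1", "smart2"):
            raise ValueError("method must be 'smart1' or 'smart2'")
        if not (0.0 < self.eps < 1.0):
            raise ValueError("eps must lie in (0, 1)")
        if self.gamma <= 1.0:
            raise ValueError("gamma must exceed 1")
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if self.cov_structure is not None:
            self.cov_structure = CovStructure(self.cov_structure)

    def resolve_cov(self, d: int) -> CovStructure:
        return self.cov_structure or default_cov_structure(d)


@dataclass
class SmartResult:
    """Selected candidate, the full candidate list and the iteration log."""

    best: ClusteringCandidate
    candidates: list[ClusteringCandidate]
    trajectory: list[dict] = field(default_factory=list)

    @property
    def k_selected(self) -> int:
        return self.best.k_nz

    @property
    def labels(self) -> np.ndarray:
        return self.best.labels


def _record(
    m: DataMatrix,
    labels: np.ndarray,
    mixture: MixtureModel,
    length: float,
) -> ClusteringCandidate:
    return ClusteringCandidate(labels, mixture, mixture.k_nz, length)


def run_smart1(m: DataMatrix, cfg: SmartConfig) -> SmartResult:
    """Competitive-learning splitting-while-merging run."""
    if m.n < 4:
        raise ValueError("need at least 4 objects")
    rng = np.random.default_rng(cfg.seed)
    cov = cfg.resolve_cov(m.d)
    state = init_learner(m, rng)
    candidates: list[ClusteringCandidate] = []
    trajectory: list[dict] = []
    merges_total = 0
    returned_to_one = False
    max_iters = cfg.m_max + 40
    for iteration in range(max_iters):
        state = learn_until_converged(
            state, m, rng, eps=cfg.eps, max_epochs=cfg.max_epochs
        )
        state, labels = prune_empty(state, m)
        k_before_merge = int(labels.max())
        merged, count = merge_pass(labels, m, gamma=cfg.gamma, cov=cov)
        merges_total += count
        state = _rebuild_prototypes(state, m, labels, merged)
        # a recorded component must carry at least the quantization mass of
        # the selection criterion on top of its N/2 support margin; smaller
        # clusters cannot be coded as components and are absorbed
        floor = int(np.ceil(n_params_per_component(m.d, cov) / 2.0
                            + _MIN_QUANT_MASS))
        merged = absorb_small_clusters(merged, m, min_members=floor)
        mixture = partition_to_mixture(m, merged, cov)
        length = message_length(m, mixture)
        candidates.append(_record(m, merged, mixture, length))
        trajectory.append(
            {
                "iteration": iteration,
                "k_learned": k_before_merge,
                "k_after_merge": int(merged.max()),
                "merges_total": merges_total,
                "message_length": length,
            }
        )
        if merges_total >= cfg.m_max:
            break
        k_now = int(merged.max())
        if k_now == 1:
            if returned_to_one:
                logger.info("split/merge oscillation at K=1; terminating")
                break
            returned_to_one = True
        try:
            state, current = prune_empty(state, m)
            state = split_largest_variance(state, m, current)
        except ValueError as exc:
            logger.info("stopping early: %s", exc)
            break
    best = select_best(candidates)
    return SmartResult(best, candidates, trajectory)


def _rebuild_prototypes(
    state: OptocState,
    m: DataMatrix,
    labels_before: np.ndarray,
    labels_after: np.ndarray,
) -> OptocState:
    """After merging, keep untouched prototypes and replace each merged
    group's prototypes by the union centroid; reset APV/DPV for re-learning."""
    k_after = int(labels_after.max())
    protos: list[np.ndarray] = []
    for c in range(1, k_after + 1):
        members = np.flatnonzero(labels_after == c)
        sources = np.unique(labels_before[members])
        if sources.size == 1 and sources[0] <= state.k:
            protos.append(state.prototypes[int(sources[0]) - 1].copy())
        else:
            protos.append(m.values[members].mean(axis=0))
    apv, dpv, na, nd = [], [], [], []
    for c, p in enumerate(protos):
        members = np.flatnonzero(labels_after == c + 1)
        far = members[np.argmax(np.linalg.norm(m.values[members] - p, axis=1))]
        apv.append(m.values[far].copy())
        dpv.append(p.copy())
        na.append(0)
        nd.append(0)
    return OptocState(protos, apv, dpv, na, nd, state.data_scale)


def _initial_mixture(
    m: DataMatrix, cov: CovStructure, rng: np.random.Generator
) -> MixtureModel:
    """k=2 start: two distinct random rows as means, with small spherical
    covariances (a tenth of the mean per-feature variance).

    Starting tight and local lets each component grow onto coherent nearby
    structure; broad initial covariances instead straddle several clusters
    and bias the two-component fit toward axis-split local optima that
    poison every later split.
    """
    idx = rng.choice(m.n, size=2, replace=False)
    while np.allclose(m.values[idx[0]], m.values[idx[1]]):
        idx[1] = int(rng.integers(m.n))
    s2 = float(m.values.var(axis=0).mean()) / 10.0
    init_cov = regularize_covariance(s2 * np.eye(m.d))
    comps = [
        GaussianComponent(0.5, m.values[i].copy(), init_cov.copy())
        for i in idx
    ]
    return MixtureModel(comps, cov)


def _mixture_candidate(
    m: DataMatrix, mix: MixtureModel
) -> ClusteringCandidate:
    """Record a mixture as a candidate; components that win no points under
    the hard assignment are dropped (weights renormalized)."""
    labels = hard_labels(m, mix)
    k_lab = int(labels.max())
    if k_lab != mix.k_nz:
        # a component won no points under the hard assignment: drop it
        live = [c for c in mix.components if c.weight > 0]
        dens = np.stack(
            [np.log(c.weight) + logpdf_rows(m.values, c.mean, c.covariance)
             for c in live], axis=1,
        )
        winners = np.unique(np.argmax(dens, axis=1))
        kept = [live[int(i)] for i in winners]
        total = sum(c.weight for c in kept)
        comps = [
            GaussianComponent(c.weight / total, c.mean, c.covariance)
            for c in kept
        ]
        mix = MixtureModel(comps, mix.cov_structure)
        labels = hard_labels(m, mix)
    length = message_length(m, mix)
    return _record(m, labels, mix, length)


def run_smart2(m: DataMatrix, cfg: SmartConfig) -> SmartResult:
    """Mixture-model splitting-while-merging run."""
    if m.n < 4:
        raise ValueError("need at least 4 objects")
    rng = np.random.default_rng(cfg.seed)
    cov = cfg.resolve_cov(m.d)
    candidates: list[ClusteringCandidate] = []
    trajectory: list[dict] = []

    # the k=1 candidate needs no learning but stays in the candidate list
    mean = m.values.mean(axis=0)
    single = MixtureModel(
        [GaussianComponent(1.0, mean, estimate_covariance(m.values, mean, cov))],
        cov,
    )
    labels1 = np.ones(m.n, dtype=int)
    candidates.append(_record(m, labels1, single, message_length(m, single)))

    mix = _initial_mixture(m, cov, rng)
    merges_total = 0
    injected = False
    max_iters = cfg.m_max + 60
    for iteration in range(max_iters):
        try:
            mix, trace, merges = cem2_run(
                m, mix, tol=cfg.tol, max_sweeps=cfg.max_sweeps,
                hold_component=mix.k - 1 if injected else None,
                hold_sweeps=cfg.hold_sweeps if injected else 0,
            )
        except AllComponentsAnnihilated:
            logger.info("all components annihilated; falling back to "
                        "recorded candidates")
            break
        merges_total += merges
        cand = _mixture_candidate(m, mix)
        candidates.append(cand)
        trajectory.append(
            {
                "iteration": iteration,
                "k_nz": mix.k_nz,
                "merges_total": merges_total,
                "sweeps": len(trace.records),
                "message_length": cand.message_length,
            }
        )
        if merges_total >= cfg.m_max:
            break
        mix = split_inject(m, cand.mixture)
        injected = True
    best = select_best(candidates)
    return SmartResult(best, candidates, trajectory)


def run(m: DataMatrix, cfg: SmartConfig) -> SmartResult:
    """Dispatch on ``cfg.method``."""
    if cfg.method == "smart1":
        return run_smart1(m, cfg)
    return run_smart2(m, cfg)
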