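"""Minimum-message-length scoring and clustering selection.

A clustering is encoded as a two-part message: the mixture parameters, then
the data given the parameters.  For a k-component Gaussian mixture with
surviving weights alpha_m and N free parameters per component, the code
length (in nats) is

    L(theta, Y) = (N/2) * sum_{m: alpha_m > 0} ln(n * alpha_m / 12)
                + (k_nz / 2) * ln(n / 12)
                + k_nz * (N + 1) / 2
                - ln p(Y | theta)

with the 1/12 quantization constants of the underlying derivation.
Zero-weight (annihilated) components are excluded.  The candidate with the
minimal length wins; ties break toward fewer clusters, then earlier
recording order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import (
    CovStructure,
    DataMatrix,
    GaussianComponent,
    MixtureModel,
    logpdf_rows,
    validate_labels,
)
from .cohesion import fit_cluster_gaussian, _absorb_singletons

__all__ = [
    "ClusteringCandidate",
    "n_params_per_component",
    "mixture_loglik",
    "message_length",
    "partition_to_mixture",
    "select_best",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class ClusteringCandidate:
    """A recorded partition with its fitted mixture and message length."""

    labels: np.ndarray
    mixture: MixtureModel
    k_nz: int
    message_length: float

    def __post_init__(self) -> None:
        self.labels = validate_labels(self.labels)
        if not np.isfinite(self.message_length):
            raise ValueError("message length must be finite")


def n_params_per_component(d: int, cov: CovStructure) -> int:
    """Free parameters per Gaussian component for each covariance structure."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if cov == CovStructure.FULL:
        return d + d * (d + 1) // 2
    if cov == CovStructure.DIAGONAL:
        return 2 * d
    if cov == CovStructure.SPHERICAL:
        return d + 1
    raise ValueError(f"unknown covariance structure {cov}")  # pragma: no cover


def mixture_loglik(m: DataMatrix, mix: MixtureModel) -> float:
    """Total log-likelihood of the data under the mixture (log-space)."""
    live = [c for c in mix.components if c.weight > 0]
    if not live:
        raise ValueError("mixture has no surviving components")
    logp = np.stack(
        [np.log(c.weight) + logpdf_rows(m.values, c.mean, c.covariance)
         for c in live],
        axis=1,
    )
    return float(np.sum(logsumexp(logp, axis=1)))


def message_length(m: DataMatrix, mix: MixtureModel) -> float:
    """Two-part MML code length (nats) of the mixture on the data."""
    n = m.n
    live_w = np.array([c.weight for c in mix.components if c.weight > 0])
    if live_w.size < 1:
        raise ValueError("mixture needs at least one surviving component")
    k_nz = live_w.size
    big_n = n_params_per_component(m.d, mix.cov_structure)
    loglik = mixture_loglik(m, mix)
    if not np.isfinite(loglik):
        raise ValueError("non-finite mixture log-likelihood")
    return float(
        0.5 * big_n * np.sum(np.log(n * live_w / 12.0))
        + 0.5 * k_nz * np.log(n / 12.0)
        + 0.5 * k_nz * (big_n + 1)
        - loglik
    )


def partition_to_mixture(
    m: DataMatrix, labels: np.ndarray, cov: CovStructure,
    min_members: int = 2,
) -> MixtureModel:
    """Gaussian refit of a hard partition: weight = cluster fraction, mean and
    covariance fit to the members.  Clusters smaller than ``min_members``
    (at least singletons) are absorbed into the nearest cluster (logged)
    before fitting."""
    labels = validate_labels(labels, m.n)
    labels = _absorb_singletons(labels, m, min_members=min_members)
    k = int(labels.max())
    comps = []
    for c in range(k):
        members = np.flatnonzero(labels == c + 1)
        comps.append(fit_cluster_gaussian(m, members, cov))
    total = sum(c.weight for c in comps)
    for c in comps:
        c.weight /= total
    return MixtureModel(comps, cov)


def select_best(cands: list[ClusteringCandidate]) -> ClusteringCandidate:
    """Candidate with minimal message length; ties -> smaller k, then first."""
    if not cands:
        raise ValueError("no candidates to select from")
    best = cands[0]
    for cand in cands[1:]:
        if cand.message_length < best.message_length or (
            cand.message_length == best.message_length and cand.k_nz < best.k_nz
        ):
            best = cand
    return best
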