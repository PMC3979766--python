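"""Modified component-wise EM (CEM2) for finite Gaussian mixtures.

Components are updated one at a time.  A Dirichlet-type prior on the mixing
weights turns the weight M-step into

    alpha_m = max(0, sum_i w_im - N/2) / sum_j max(0, sum_i w_ij - N/2)

where N is the number of free parameters per component: a component whose
expected support falls below N/2 is annihilated (its weight hits zero and
it is removed), so learning and merging happen in the same sweep.  The
deterministic split step injects a new component at the data row farthest
from its closest surviving mean, with the element-wise average of the
surviving covariances and weight 1/(k+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    CovStructure,
    DataMatrix,
    GaussianComponent,
    MixtureModel,
    estimate_covariance,
    logpdf_rows,
)
from .mml import message_length, n_params_per_component

__all__ = [
    "AllComponentsAnnihilated",
    "Cem2Trace",
    "estep",
    "annihilating_weight_update",
    "mstep_component",
    "cem2_run",
    "injection_site",
    "split_inject",
    "hard_labels",
]

logger = logging.getLogger(__name__)


class AllComponentsAnnihilated(RuntimeError):
    """Raised when the weight update zeroes every component at once."""


#: Quantization mass of the message-length criterion: a surviving
#: component's expected sample size n*alpha must be at least this for its
#: parameter-cost term ln(n*alpha/12) to be non-negative.
_MIN_QUANT_MASS = 12.0


@dataclass
class Cem2Trace:
    """Per-sweep log: (sweep index, message length, k_nz, annihilations)."""

    records: list[tuple[int, float, int, int]] = field(default_factory=list)

    def append(self, sweep: int, length: float, k_nz: int, events: int) -> None:
        self.records.append((sweep, length, k_nz, events))

    @property
    def lengths(self) -> list[float]:
        return [r[1] for r in self.records]


def _log_joint(m: DataMatrix, mix: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """log(alpha_m p(y|theta_m)) for live components; returns (logp, live_idx)."""
    live = np.flatnonzero(mix.weights > 0)
    cols = []
    for j in live:
        c = mix.components[j]
        cols.append(np.log(c.weight) + logpdf_rows(m.values, c.mean, c.covariance))
    return np.stack(cols, axis=1), live


def estep(m: DataMatrix, mix: MixtureModel) -> np.ndarray:
    """Responsibilities w_im = alpha_m p(y_i|m) / sum_j alpha_j p(y_i|j).

    Computed in log space; columns of zero-weight components are zero.  Rows
    where every density underflows are assigned uniformly over the live
    components (with a warning).
    """
    logp, live = _log_joint(m, mix)
    norm = logsumexp(logp, axis=1)
    w_live = np.exp(logp - norm[:, None])
    bad = ~np.isfinite(norm)
    if np.any(bad):
        logger.warning("density underflow on %d rows; assigning uniformly",
                       int(bad.sum()))
        w_live[bad] = 1.0 / live.size
    w = np.zeros((m.n, mix.k))
    w[:, live] = w_live
    return w


def annihilating_weight_update(w: np.ndarray, n_params: int) -> np.ndarray:
    """Dirichlet-prior weight M-step with component annihilation.

    Applies max(0, column_sum - N/2) to every component column and
    renormalizes over the survivors; a zero entry means that component is
    annihilated.  Raises when every numerator is zero.
    """
    col = np.asarray(w, dtype=float).sum(axis=0)
    num = np.maximum(0.0, col - n_params / 2.0)
    total = num.sum()
    if total <= 0.0:
        raise AllComponentsAnnihilated(
            "all components annihilated: every expected support is below N/2"
        )
    return num / total


def mstep_component(
    m: DataMatrix,
    w: np.ndarray,
    m_index: int,
    cov: CovStructure,
) -> GaussianComponent:
    """Weighted-MLE update of one component's mean and covariance."""
    wm = np.asarray(w, dtype=float)[:, m_index]
    support = float(wm.sum())
    if support < 2.0:
        raise ValueError(
            f"component {m_index} has effective weight {support:.3f} < 2; "
            "insufficient support for a covariance estimate"
        )
    mean = (wm[:, None] * m.values).sum(axis=0) / support
    covariance = estimate_covariance(m.values, mean, cov, weights=wm)
    return GaussianComponent(1.0, mean, covariance)


def _live_mixture(
    weights: np.ndarray, means: list[np.ndarray], covs: list[np.ndarray],
    structure: CovStructure,
) -> MixtureModel:
    live = np.flatnonzero(weights > 0)
    total = weights[live].sum()
    comps = [
        GaussianComponent(weights[j] / total, means[j], covs[j]) for j in live
    ]
    return MixtureModel(comps, structure)


def cem2_run(
    m: DataMatrix,
    mix: MixtureModel,
    tol: float = 1e-5,
    max_sweeps: int = 500,
    hold_component: int | None = None,
    hold_sweeps: int = 0,
) -> tuple[MixtureModel, Cem2Trace, int]:
    """Run component-wise sweeps until the message length stabilizes.

    One sweep visits every surviving component in turn: responsibilities,
    the annihilating update of that component's weight (the other weights
    are rescaled so the total stays 1), then — if it survived — its M-step
    and a refresh of its cached densities.  Only the component whose turn
    it is can be annihilated at that turn; this component-wise schedule
    lets a weak component recover over later sweeps when it genuinely
    explains an uncovered region, while a component parked on territory the
    others already explain sees its support decay sweep by sweep until it
    is removed.  Returns the surviving mixture, the per-sweep trace and the
    number of annihilation events (the run's merge count).

    ``hold_component``/``hold_sweeps``: the named component keeps its
    current weight (the others are rescaled into the remaining mass) while
    its mean and covariance adapt freely, until its mean settles (movement
    below 1e-3 of the data radius between sweeps) or ``hold_sweeps`` sweeps
    have passed, whichever comes first.  A component injected at a far data
    row starts with no basin of support; holding its weight through this
    establishment phase lets it migrate onto structure the incumbents do
    not explain before the support-based weight update judges it, while a
    component that settles quickly onto already-covered territory is judged
    early.
    """
    structure = mix.cov_structure
    n_params = n_params_per_component(m.d, structure)
    weights = mix.weights.copy()
    means = [c.mean.copy() for c in mix.components]
    covs = [c.covariance.copy() for c in mix.components]
    k = len(means)
    # cached log densities per component (alpha-free)
    logdens = np.full((m.n, k), -np.inf)
    for j in range(k):
        if weights[j] > 0:
            logdens[:, j] = logpdf_rows(m.values, means[j], covs[j])

    trace = Cem2Trace()
    merges = 0
    prev_len = None
    center = m.values.mean(axis=0)
    data_radius = float(np.max(np.linalg.norm(m.values - center, axis=1)))
    settle_tol = 1e-3 * max(data_radius, 1e-12)
    hold_active = hold_component is not None and hold_sweeps > 0
    prev_hold_mean = (
        means[hold_component].copy() if hold_active else None
    )
    for sweep in range(max_sweeps):
        events = 0
        for j in range(k):
            if weights[j] <= 0:
                continue
            live = np.flatnonzero(weights > 0)

            def _resp(live_idx):
                logp = logdens[:, live_idx] + np.log(weights[live_idx])
                norm = logsumexp(logp, axis=1)
                w_live = np.exp(logp - norm[:, None])
                bad = ~np.isfinite(norm)
                if np.any(bad):
                    w_live[bad] = 1.0 / live_idx.size
                return w_live

            w_live = _resp(live)
            col = int(np.flatnonzero(live == j)[0])
            holding = hold_active and weights[hold_component] > 0
            if not (holding and j == hold_component):
                # component-wise weight M-step with annihilation: only
                # component j's weight is re-estimated at its turn; the
                # rest are rescaled to keep the total at 1.  Beyond the
                # Dirichlet-prior N/2 margin, a survivor must carry at
                # least the quantization mass of the message-length
                # criterion (n * alpha >= 12), i.e. its parameter-cost
                # term must be non-negative; below that the criterion's
                # approximation is invalid and rewards spurious tiny
                # components.
                support = w_live[:, col].sum() - n_params / 2.0
                alpha_j = support / m.n if support >= _MIN_QUANT_MASS else 0.0
                weights[j] = alpha_j
                total = weights[live].sum()
                if total <= 0.0:
                    raise AllComponentsAnnihilated(
                        "all components annihilated: every expected support "
                        "fell below N/2"
                    )
                if holding:
                    # rescale the others into the mass the held component
                    # does not occupy
                    held = weights[hold_component]
                    others = [i for i in live if i != hold_component]
                    other_total = weights[others].sum()
                    if other_total > 0:
                        weights[others] *= (1.0 - held) / other_total
                else:
                    weights[live] /= total
                if alpha_j == 0.0:
                    events += 1
                    logdens[:, j] = -np.inf
                    continue
            w_live = _resp(live)
            if w_live[:, col].sum() >= 2.0:
                comp = mstep_component(m, w_live, col, structure)
                means[j] = comp.mean
                covs[j] = comp.covariance
                logdens[:, j] = logpdf_rows(m.values, means[j], covs[j])
        if hold_active:
            moved = float(
                np.linalg.norm(means[hold_component] - prev_hold_mean)
            )
            prev_hold_mean = means[hold_component].copy()
            if moved < settle_tol or sweep + 1 >= hold_sweeps:
                hold_active = False
        merges += events
        current = _live_mixture(weights, means, covs, structure)
        length = message_length(m, current)
        trace.append(sweep, length, current.k_nz, events)
        if (
            prev_len is not None
            and events == 0
            and not hold_active
            and abs(length - prev_len) < tol * abs(prev_len)
        ):
            break
        prev_len = length
    return _live_mixture(weights, means, covs, structure), trace, merges


def injection_site(m: DataMatrix, mix: MixtureModel, exclude=()) -> int:
    """Row index of the object farthest (Euclidean) from its closest
    surviving component mean; rows in ``exclude`` are skipped."""
    live = [c for c in mix.components if c.weight > 0]
    if not live:
        raise ValueError("mixture has no surviving components")
    means = np.stack([c.mean for c in live])
    d2 = ((m.values[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    min_dist = np.sqrt(d2.min(axis=1))
    if exclude:
        keep = np.setdiff1d(np.arange(m.n), np.asarray(list(exclude)))
        if keep.size == 0:
            raise ValueError("every row is excluded from injection")
        masked = np.full(m.n, -np.inf)
        masked[keep] = min_dist[keep]
        min_dist = masked
    return int(np.argmax(min_dist))


def split_inject(
    m: DataMatrix, mix: MixtureModel, exclude=(), site: int | None = None
) -> MixtureModel:
    """Inject a new component at the data row farthest from its closest
    surviving mean; covariance = average of surviving covariances; the
    newcomer takes weight 1/(k+1) and survivors are rescaled.

    Rows listed in ``exclude`` (e.g. sites whose previous injection was
    annihilated) are skipped when choosing the target; ``site`` overrides
    the choice with an explicit row index.
    """
    live = [c for c in mix.components if c.weight > 0]
    if not live:
        raise ValueError("mixture has no surviving components")
    means = np.stack([c.mean for c in live])
    star = injection_site(m, mix, exclude) if site is None else int(site)
    min_to_mean = float(np.min(np.linalg.norm(means - m.values[star], axis=1)))
    new_mean = m.values[star].copy()
    if min_to_mean == 0.0:
        center = m.values.mean(axis=0)
        scale = float(np.max(np.linalg.norm(m.values - center, axis=1)))
        rng = np.random.default_rng(star)
        new_mean = new_mean + 1e-6 * max(scale, 1.0) * rng.standard_normal(m.d)
        logger.info("split target coincides with an existing mean; perturbed")
    new_cov = np.mean([c.covariance for c in live], axis=0)
    k = len(live)
    comps = [
        GaussianComponent(c.weight * (1.0 - 1.0 / (k + 1)), c.mean.copy(),
                          c.covariance.copy())
        for c in live
    ]
    comps.append(GaussianComponent(1.0 / (k + 1), new_mean, new_cov))
    return MixtureModel(comps, mix.cov_structure)


def hard_labels(m: DataMatrix, mix: MixtureModel) -> np.ndarray:
    """Maximum-posterior hard assignment, compacted to contiguous 1..K."""
    logp, live = _log_joint(m, mix)
    raw = live[np.argmax(logp, axis=1)]
    used = np.unique(raw)
    remap = {int(old): new + 1 for new, old in enumerate(used)}
    return np.array([remap[int(r)] for r in raw], dtype=int)
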