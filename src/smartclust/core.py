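"""Shared data containers and Gaussian density utilities.

The clustering substrate is an objects-by-features matrix (rows are genes or
signal samples, columns are experimental samples or coordinates).  Cluster
models are finite Gaussian mixtures whose covariance matrices may be
constrained to one of three structures: ``full`` (unconstrained symmetric
positive definite), ``diagonal`` (independent per-feature variances) or
``spherical`` (a single isotropic variance).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "CovStructure",
    "DataMatrix",
    "GaussianComponent",
    "MixtureModel",
    "standardize_rows",
    "gaussian_logpdf",
    "logpdf_rows",
    "regularize_covariance",
    "estimate_covariance",
    "validate_labels",
]

#: Ridge added to every estimated covariance: eps * mean(diagonal) * I.
#: Guards against singular fits on high-dimensional matrices with small
#: clusters.
RIDGE_EPS = 1e-6


class CovStructure(str, enum.Enum):
    """Covariance structure tag for mixture components."""

    FULL = "full"
    DIAGONAL = "diagonal"
    SPHERICAL = "spherical"


@dataclass
class DataMatrix:
    """An n-objects x d-features real matrix with unique row identifiers."""

    values: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 objects, got {n}")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite entry at row {bad[0]}, column {bad[1]}"
            )
        self.row_ids = [str(r) for r in self.row_ids]
        if len(self.row_ids) != n:
            raise ValueError("row_ids length must match number of rows")
        if len(set(self.row_ids)) != n:
            seen: set[str] = set()
            for r in self.row_ids:
                if r in seen:
                    raise ValueError(f"duplicate row id: {r!r}")
                seen.add(r)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values, row_ids=None) -> "DataMatrix":
        values = np.asarray(values, dtype=float)
        if row_ids is None:
            width = max(4, len(str(values.shape[0])))
            row_ids = [f"g{i + 1:0{width}d}" for i in range(values.shape[0])]
        return cls(values, list(row_ids))


def validate_labels(labels, n: int | None = None) -> np.ndarray:
    """Check that ``labels`` is a contiguous 1..K assignment; return as array."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValueError("labels must be 1-d")
    if n is not None and labels.size != n:
        raise ValueError(f"labels length {labels.size} != n {n}")
    uniq = np.unique(labels)
    k = uniq.size
    if not np.array_equal(uniq, np.arange(1, k + 1)):
        raise ValueError("labels must be contiguous integers 1..K")
    return labels


def standardize_rows(m: DataMatrix) -> DataMatrix:
    """Scale every row to zero mean and unit sample standard deviation.

    Uses the n-1 denominator.  Idempotent; raises on constant rows.
    """
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0.0)
    if zero.size:
        raise ValueError(
            f"zero-variance row cannot be standardized: {m.row_ids[zero[0]]!r}"
        )
    return DataMatrix((m.values - mu) / sd, list(m.row_ids))


@dataclass
class GaussianComponent:
    """One mixture component: weight, mean and a d x d covariance.

    The covariance is always stored dense and symmetric; structural
    constraints (diagonal, spherical) are enforced at estimation time.
    """

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")
        d = self.mean.size
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape must match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class MixtureModel:
    """Ordered finite Gaussian mixture with a covariance-structure tag."""

    components: list[GaussianComponent]
    cov_structure: CovStructure = CovStructure.FULL

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def k_nz(self) -> int:
        return sum(1 for c in self.components if c.weight > 0)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def d(self) -> int:
        return self.components[0].mean.size


def regularize_covariance(cov: np.ndarray, eps: float = RIDGE_EPS) -> np.ndarray:
    """Add a ridge eps * mean(diag) * I (falls back to eps*I on a zero trace)."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    scale = float(np.mean(np.diag(cov)))
    if scale <= 0.0:
        scale = 1.0
    return cov + eps * scale * np.eye(cov.shape[0])


def estimate_covariance(
    x: np.ndarray,
    mean: np.ndarray,
    structure: CovStructure,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted covariance of ``x`` about ``mean``, structured and regularized.

    Weights default to uniform and are normalized internally.  The result is
    a dense d x d matrix even for diagonal/spherical tags.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = x.shape[1]
    if weights is None:
        weights = np.full(x.shape[0], 1.0 / x.shape[0])
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    diff = x - np.asarray(mean, dtype=float)
    if structure == CovStructure.FULL:
        cov = (diff * weights[:, None]).T @ diff
    elif structure == CovStructure.DIAGONAL:
        cov = np.diag(np.sum(weights[:, None] * diff**2, axis=0))
    elif structure == CovStructure.SPHERICAL:
        var = float(np.sum(weights[:, None] * diff**2) / d)
        cov = var * np.eye(d)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown covariance structure {structure}")
    return regularize_covariance(cov)


def _cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance matrix; regularize it first "
            "(see regularize_covariance)"
        ) from exc


_LOG_2PI = float(np.log(2.0 * np.pi))


def logpdf_rows(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate-normal log density of every row of ``x``; vectorized."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = mean.size
    chol = _cholesky(cov)
    diff = x - mean
    z = solve_triangular(chol, diff.T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * _LOG_2PI + logdet + np.sum(z**2, axis=0))


def gaussian_logpdf(x: np.ndarray, c: GaussianComponent) -> float:
    """Log density of a single point under one Gaussian component."""
    return float(logpdf_rows(np.atleast_1d(x)[None, :], c.mean, c.covariance)[0])
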