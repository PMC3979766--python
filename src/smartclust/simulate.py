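"""Synthetic dataset generators with known cluster truth.

Four generator families:

* ``gen_qpsk`` — a quadrature phase-shift keying constellation: four unit
  energy symbols at (+-1/sqrt2, +-1/sqrt2) plus white Gaussian noise, a
  planar 4-component Gaussian mixture parameterized by SNR (Es/N0, so the
  per-dimension noise variance is 10^(-SNR/10)/2).
* ``gen_gmm`` — arbitrary finite Gaussian mixtures; the default is the
  overlapping 3-component bivariate demonstration: equal weights, collinear
  means two units apart on one axis, a shared diagonal covariance
  diag(4, 0.4) (the classic demonstration's diag(2, 0.2), doubled).
* ``gen_s1`` — state-based gene expression: clusters of Poisson-distributed
  size whose profiles follow a hierarchical normal model on the log scale
  (cluster template over four contiguous expression periods -> per-sample
  template -> per-gene values) plus additive measurement noise.
* ``gen_s2`` — periodic cell-cycle expression: gene g in cluster c at
  sample j has value (lam + theta_mag*u) * sin(2*pi*j/8 + omega_c +
  theta_phase*v) with u, v independent standard normals and equally spaced
  cluster phases omega_c = 2*pi*c/k; the 8-sample period makes 24 samples
  span three cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataMatrix

__all__ = [
    "QpskSpec",
    "GmmSpec",
    "S1Spec",
    "S2Spec",
    "gen_qpsk",
    "gen_gmm",
    "gen_s1",
    "gen_s2",
]

_QPSK_CORNERS = np.array(
    [[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float
) / np.sqrt(2.0)


@dataclass
class QpskSpec:
    n: int = 512
    snr_db: float = 15.0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def gen_qpsk(
    spec: QpskSpec, rng: np.random.Generator
) -> tuple[DataMatrix, np.ndarray]:
    """Unit-energy QPSK symbols with additive white Gaussian noise."""
    sym = rng.integers(4, size=spec.n)
    sigma2 = 10.0 ** (-spec.snr_db / 10.0) / 2.0
    x = _QPSK_CORNERS[sym] + np.sqrt(sigma2) * rng.standard_normal((spec.n, 2))
    return DataMatrix.from_array(x), sym + 1


def _d2_default_means() -> list[np.ndarray]:
    return [np.array([0.0, -2.0]), np.array([0.0, 0.0]), np.array([0.0, 2.0])]


@dataclass
class GmmSpec:
    weights: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))
    means: list[np.ndarray] = field(default_factory=_d2_default_means)
    covariances: list[np.ndarray] = field(
        default_factory=lambda: [np.diag([4.0, 0.4])] * 3)
    n: int = 900

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        self.means = [np.atleast_1d(np.asarray(mu, dtype=float))
                      for mu in self.means]
        self.covariances = [np.atleast_2d(np.asarray(c, dtype=float))
                            for c in self.covariances]
        if not (len(self.means) == len(self.covariances)
                == self.weights.size):
            raise ValueError("weights/means/covariances must align")
        d = self.means[0].size
        for cov in self.covariances:
            if cov.shape != (d, d):
                raise ValueError("covariance dimensions inconsistent")
            eig = np.linalg.eigvalsh(cov)
            if np.any(eig < -1e-12):
                raise ValueError("covariance must be positive semi-definite")


def gen_gmm(
    spec: GmmSpec, rng: np.random.Generator
) -> tuple[DataMatrix, np.ndarray]:
    """Sample a finite Gaussian mixture; labels are component indices."""
    comp = rng.choice(spec.weights.size, size=spec.n, p=spec.weights)
    d = spec.means[0].size
    x = np.empty((spec.n, d))
    for j in range(spec.weights.size):
        idx = np.flatnonzero(comp == j)
        if idx.size:
            x[idx] = rng.multivariate_normal(
                spec.means[j], spec.covariances[j], size=idx.size,
                method="eigh",
            )
    return DataMatrix.from_array(x), comp + 1


@dataclass
class S1Spec:
    k: int = 11
    size_mean: float = 60.0
    m_samples: int = 20
    template_sd: float = 1.5
    sample_sd: float = 0.5
    gene_sd: float = 0.5
    noise_sd: float = 0.1
    size_floor: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.m_samples < 4:
            raise ValueError("cannot form 4 expression periods with < 4 samples")
        for name in ("template_sd", "sample_sd", "gene_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _random_composition(total: int, parts: int, rng: np.random.Generator):
    """Uniform random composition of ``total`` into ``parts`` pieces >= 1."""
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1,
                              replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return np.diff(bounds)


def gen_s1(
    spec: S1Spec, rng: np.random.Generator
) -> tuple[DataMatrix, np.ndarray]:
    """State-based expression profiles: hierarchical cluster/sample/gene
    normal draws over four contiguous periods, plus additive noise."""
    rows, labels = [], []
    for c in range(spec.k):
        size = max(spec.size_floor, int(rng.poisson(spec.size_mean)))
        period_sizes = _random_composition(spec.m_samples, 4, rng)
        template = np.repeat(
            rng.normal(0.0, spec.template_sd, size=4), period_sizes
        )
        sample_template = rng.normal(template, spec.sample_sd)
        genes = rng.normal(
            sample_template, spec.gene_sd, size=(size, spec.m_samples)
        )
        genes += rng.normal(0.0, spec.noise_sd, size=genes.shape)
        rows.append(genes)
        labels.append(np.full(size, c + 1))
    return (
        DataMatrix.from_array(np.vstack(rows)),
        np.concatenate(labels).astype(int),
    )


@dataclass
class S2Spec:
    g: int = 500
    m: int = 24
    k: int = 5
    lam: float = 3.0
    theta_mag: float = 0.1
    theta_phase: float = 0.1
    period: int = 8

    def __post_init__(self) -> None:
        if self.g % self.k:
            raise ValueError("g must be divisible by k")
        if self.m < 8:
            raise ValueError("m must be >= 8")


def gen_s2(
    spec: S2Spec, rng: np.random.Generator
) -> tuple[DataMatrix, np.ndarray]:
    """Cyclic expression: amplitude- and phase-perturbed sinusoids with
    equally spaced cluster phases."""
    per = spec.g // spec.k
    j = np.arange(spec.m)
    labels = np.repeat(np.arange(spec.k), per)
    omega = 2.0 * np.pi * labels / spec.k
    u = rng.standard_normal((spec.g, spec.m))
    v = rng.standard_normal((spec.g, spec.m))
    phase = 2.0 * np.pi * j / spec.period + omega[:, None] \
        + spec.theta_phase * v
    x = (spec.lam + spec.theta_mag * u) * np.sin(phase)
    return DataMatrix.from_array(x), labels + 1
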