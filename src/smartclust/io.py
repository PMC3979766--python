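"""File readers/writers and the reduced-scale replication harness."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataMatrix, validate_labels
from .metrics import (
    adjusted_rand_index,
    correct_selection_rate,
    jaccard_index,
    normalized_mutual_information,
)
from .simulate import (
    GmmSpec,
    QpskSpec,
    S1Spec,
    S2Spec,
    gen_gmm,
    gen_qpsk,
    gen_s1,
    gen_s2,
)
from .smart import SmartConfig, run

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "RunManifest",
    "write_manifest",
    "replicate_experiment",
]

_DELIMS = {"tab": "\t", "comma": ","}


def read_matrix(path, delimiter: str = "tab", has_header: bool = True) -> DataMatrix:
    """Read an objects-by-features table whose first column is the row id."""
    sep = _DELIMS.get(delimiter)
    if sep is None:
        raise ValueError("delimiter must be 'tab' or 'comma'")
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate row id: {dup[0]!r}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at row {ids[r]!r}, column {c + 1}"
        )
    return DataMatrix(values, ids)


def write_matrix(path, m: DataMatrix, delimiter: str = "tab") -> None:
    sep = _DELIMS[delimiter]
    df = pd.DataFrame(
        m.values, index=m.row_ids,
        columns=[f"s{j + 1}" for j in range(m.d)],
    )
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def write_labels(path, ids, labels) -> None:
    labels = np.asarray(labels, dtype=int)
    if len(ids) != labels.size:
        raise ValueError("ids and labels must have equal length")
    pd.DataFrame({"id": list(ids), "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    labels = df.iloc[:, 1].astype(int).to_numpy()
    validate_labels(labels)
    return [str(i) for i in df.iloc[:, 0]], labels


@dataclass
class RunManifest:
    """Plain-text record sufficient to replay a clustering run exactly."""

    config: dict
    seed: int
    input_digest: str
    candidates: list[tuple[int, float]]
    selected_k: int
    metrics: dict = field(default_factory=dict)


def matrix_digest(m: DataMatrix) -> str:
    h = hashlib.sha256()
    h.update("\n".join(m.row_ids).encode())
    h.update(np.ascontiguousarray(m.values).tobytes())
    return h.hexdigest()[:16]


def write_manifest(path, manifest: RunManifest) -> None:
    lines = [f"seed={manifest.seed}", f"input_digest={manifest.input_digest}"]
    for key, val in sorted(manifest.config.items()):
        lines.append(f"config.{key}={val}")
    lines.append(f"selected_k={manifest.selected_k}")
    for key, val in sorted(manifest.metrics.items()):
        lines.append(f"metric.{key}={val}")
    lines.append("candidates:\tk\tmessage_length")
    for k, length in manifest.candidates:
        lines.append(f"candidate\t{k}\t{length:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_EXPERIMENTS = {"d1", "d2", "s1_sweep", "s2_sweep"}


def _gen_for(name: str, rng: np.random.Generator, noise=None):
    if name == "d1":
        return gen_qpsk(QpskSpec(), rng), 4
    if name == "d2":
        return gen_gmm(GmmSpec(), rng), 3
    if name.startswith("s1"):
        spec = S1Spec() if noise is None else S1Spec(noise_sd=noise)
        data, truth = gen_s1(spec, rng)
        return (data, truth), spec.k
    spec = S2Spec() if noise is None else S2Spec(theta_mag=noise,
                                                 theta_phase=noise)
    data, truth = gen_s2(spec, rng)
    return (data, truth), spec.k


def replicate_experiment(
    name: str,
    reps: int = 20,
    seed: int = 0,
    method: str = "smart2",
    noise_grid=None,
    m_max: int = 5,
) -> pd.DataFrame:
    """Re-run one of the simulation experiments at reduced scale.

    Returns a long-format table with one row per replicate (columns: name,
    noise, rep, k_hat, ari, ji, nmi) plus aggregate rows carrying the mean,
    standard deviation and correct selection rate per condition.
    """
    if name not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(_EXPERIMENTS)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if noise_grid is None:
        noise_grid = [None] if name in ("d1", "d2") else (
            [0.0, 0.1, 0.2] if name == "s1_sweep" else [0.1, 0.5, 1.0]
        )
    rows = []
    root = np.random.SeedSequence(seed)
    for noise in noise_grid:
        k_hats = []
        for rep, child in enumerate(root.spawn(reps)):
            rng = np.random.default_rng(child)
            (data, truth), k_true = _gen_for(name, rng, noise)
            run_seed = int(rng.integers(2**31 - 1))
            cfg = SmartConfig(method=method, seed=run_seed, m_max=m_max)
            result = run(data, cfg)
            k_hats.append(result.k_selected)
            rows.append({
                "experiment": name,
                "noise": np.nan if noise is None else noise,
                "rep": rep,
                "k_true": k_true,
                "k_hat": result.k_selected,
                "ari": adjusted_rand_index(truth, result.labels),
                "ji": jaccard_index(truth, result.labels),
                "nmi": normalized_mutual_information(truth, result.labels),
            })
        csr = correct_selection_rate(k_hats, k_true)
        sub = [r for r in rows if r["experiment"] == name
               and (noise is None or r["noise"] == noise)
               and r["rep"] >= 0]
        rows.append({
            "experiment": name,
            "noise": np.nan if noise is None else noise,
            "rep": -1,  # aggregate row
            "k_true": k_true,
            "k_hat": float(np.mean(k_hats)),
            "ari": float(np.mean([r["ari"] for r in sub])),
            "ji": float(np.mean([r["ji"] for r in sub])),
            "nmi": float(np.mean([r["nmi"] for r in sub])),
            "csr": csr,
            "ari_sd": float(np.std([r["ari"] for r in sub]))
            if reps > 1 else np.nan,
        })
    return pd.DataFrame(rows)
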