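"""Principal component analysis with explained-variance component selection.

Deterministic SVD-based PCA on the centered binary exposure matrix.  The
component count is the smallest number of components whose cumulative
explained-variance ratio exceeds a target fraction (default 0.70),
optionally capped.  Binary indicator columns share a scale, so columns
are centered but not standardized.  A fixed sign convention (the
largest-magnitude loading of each component is made positive) keeps
outputs identical across runs and platforms.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "fit_pca", "transform", "inverse_transform"]

_RANK_TOL = 1e-10


@dataclass
class PCAModel:
    mean_vector: np.ndarray          # (M,)
    components: np.ndarray           # (n_components, M), orthonormal rows
    explained_variance: np.ndarray   # (n_components,)
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_target: float
    total_variance: float            # trace of the centered covariance

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "mean_vector": self.mean_vector.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
            "variance_target": self.variance_target,
            "total_variance": self.total_variance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["mean_vector"], dtype=float),
            np.asarray(d["components"], dtype=float),
            np.asarray(d["explained_variance"], dtype=float),
            np.asarray(d["explained_variance_ratio"], dtype=float),
            int(d["n_components"]),
            float(d["variance_target"]),
            float(d["total_variance"]),
        )


def fit_pca(
    X: np.ndarray,
    variance_target: float = 0.70,
    max_components: int | None = None,
) -> PCAModel:
    """Fit PCA by singular value decomposition of the centered matrix.

    ``n_components`` is the smallest n whose cumulative explained
    variance ratio strictly exceeds ``variance_target``, capped by
    ``max_components`` and by the matrix rank.  A constant (rank-0)
    matrix is rejected.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"need a 2-D matrix with >= 2 rows, got shape {X.shape}")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    P = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (P - 1)
    total = var.sum()
    if total <= _RANK_TOL:
        raise ValueError("matrix is constant across rows (rank 0 after centering); PCA undefined")
    rank = int((s > s[0] * _RANK_TOL).sum())
    ratio = var / total
    cum = np.cumsum(ratio[:rank])
    above = np.nonzero(cum > variance_target)[0]
    n = int(above[0]) + 1 if len(above) else rank
    if max_components is not None:
        n = min(n, int(max_components))
    n = min(n, rank)
    components = Vt[:n].copy()
    # sign convention: largest-|loading| entry of each component positive
    for i in range(n):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
    return PCAModel(
        mean_vector=mean,
        components=components,
        explained_variance=var[:n].copy(),
        explained_variance_ratio=ratio[:n].copy(),
        n_components=n,
        variance_target=variance_target,
        total_variance=float(total),
    )


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows onto the principal axes: ``(X - mean) @ components.T``."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"X has {X.shape[-1]} columns, model expects {model.mean_vector.shape[0]}"
        )
    return (X - model.mean_vector) @ model.components.T


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Reconstruct from scores: ``scores @ components + mean``."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[-1] != model.n_components:
        raise ValueError(
            f"scores have {scores.shape[-1]} columns, model has {model.n_components} components"
        )
    return scores @ model.components + model.mean_vector
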