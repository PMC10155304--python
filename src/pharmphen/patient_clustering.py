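"""Patient clustering on normalized pharmacophenotype distributions.

Each patient is summarized by the fraction of their distinct medication
exposures falling in each pharmacophenotype (including the unassigned
bucket K+1).  In the default fractional mode a medication belonging to
several phenotypes contributes equal fractions to each, so the vector
is a probability distribution; full mode counts overlapping memberships
whole, so rows may sum past 1.  Patients are then merged bottom-up by
hierarchical agglomerative clustering (Ward linkage on Euclidean
distances by default) and the dendrogram is cut at a chosen cluster
count, with a relative-gap heuristic standing in for visual dendrogram
inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .cdm_encoding import CohortMatrix
from .rbm_phenotyping import PhenotypeAssignment

__all__ = [
    "phenotype_distribution",
    "LinkageTree",
    "hac",
    "cut_tree",
    "suggest_k",
]

_LINKAGES = ("ward", "average", "complete", "single")


def phenotype_distribution(
    matrix: CohortMatrix,
    assignment: PhenotypeAssignment,
    mode: str = "fractional",
) -> pd.DataFrame:
    """Per-patient normalized phenotype frequency table.

    Returns a DataFrame indexed by patient with columns
    ``phenotype_1 .. phenotype_{K+1}``.  Counts are over the patient's
    distinct order keys and are divided by the patient's total distinct
    exposure count.  Every key in the matrix must be covered by the
    assignment.
    """
    if mode not in ("fractional", "full"):
        raise ValueError(f"mode must be 'fractional' or 'full', got {mode!r}")
    Kp1 = assignment.K + 1
    A = np.zeros((len(matrix.order_keys), Kp1))
    for j, key in enumerate(matrix.order_keys):
        members = assignment.membership.get(key)
        if members is None:
            raise KeyError(f"order key {key!r} missing from phenotype assignment")
        w = 1.0 / len(members) if mode == "fractional" else 1.0
        for lab in members:
            A[j, lab - 1] = w
    X = matrix.X.astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("matrix contains patients with zero exposures")
    F = (X @ A) / totals[:, None]
    cols = [f"phenotype_{i}" for i in range(1, Kp1 + 1)]
    out = pd.DataFrame(F, index=pd.Index(matrix.patients, name="patient_id"), columns=cols)
    out["total_orders"] = totals.astype(int)
    return out


def distribution_features(dist: pd.DataFrame) -> np.ndarray:
    """Feature matrix (phenotype columns only) from a distribution table."""
    cols = [c for c in dist.columns if c.startswith("phenotype_")]
    return dist[cols].to_numpy(dtype=float)


@dataclass
class LinkageTree:
    """Agglomerative merge history in the standard 4-column linkage
    matrix encoding (left, right, height, new cluster size)."""

    Z: np.ndarray
    n_leaves: int
    linkage: str
    metric: str

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


def hac(features: np.ndarray, linkage: str = "ward", metric: str = "euclidean") -> LinkageTree:
    """Hierarchical agglomerative clustering.

    Starts from singleton clusters and repeatedly merges the pair with
    the smallest linkage distance (Lance-Williams updates), producing
    the full merge tree.  Supported linkages: ward (default), average,
    complete, single — all with Euclidean distances.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError(f"need a 2-D feature matrix with >= 2 rows, got shape {F.shape}")
    if not np.isfinite(F).all():
        raise ValueError("features contain NaN or infinite values")
    Z = hierarchy.linkage(F, method=linkage, metric=metric)
    return LinkageTree(Z, F.shape[0], linkage, metric)


def cut_tree(tree: LinkageTree, n_clusters: int) -> np.ndarray:
    """Cut the dendrogram into exactly ``n_clusters`` groups.

    Returns integer labels ``1..C`` renumbered by descending cluster
    size (ties broken by the lowest member index), so label 1 is always
    the largest patient cluster.
    """
    P = tree.n_leaves
    if not 1 <= n_clusters <= P:
        raise ValueError(f"n_clusters must be in [1, {P}], got {n_clusters}")
    raw = hierarchy.fcluster(tree.Z, t=n_clusters, criterion="maxclust")
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, lab in enumerate(raw):
        sizes[lab] = sizes.get(lab, 0) + 1
        first.setdefault(lab, i)
    order = sorted(sizes, key=lambda lab: (-sizes[lab], first[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw], dtype=int)


def suggest_k(tree: LinkageTree, k_max: int = 10) -> tuple[int, pd.DataFrame]:
    """Programmatic stand-in for visual dendrogram inspection.

    For each candidate k, the relative gap is the fractional jump
    between the merge height just below a k-cluster cut and the one
    just above it: ``(h[P-k+1] - h[P-k]) / h[P-k]`` on the ascending
    height sequence.  Returns the k (2 <= k <= k_max) with the largest
    gap plus the full gap table for human override.  A degenerate tree
    with all-equal heights returns k=2 with a flat-gap warning.
    """
    import warnings

    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    P = tree.n_leaves
    h = tree.heights
    rows = []
    for k in range(2, min(k_max, P - 1) + 1):
        upper = h[P - k]       # first merge height above a k-cluster cut
        lower = h[P - k - 1]   # last merge height below it
        if lower > 0:
            gap = (upper - lower) / lower
        else:
            gap = np.inf if upper > 0 else 0.0
        rows.append({"k": k, "height_below": lower, "height_above": upper, "relative_gap": gap})
    table = pd.DataFrame(rows)
    if len(table) == 0 or np.allclose(table["relative_gap"], 0.0):
        warnings.warn("flat dendrogram: all merge gaps equal; defaulting to k=2")
        return 2, table
    best = int(table.loc[table["relative_gap"].idxmax(), "k"])
    return best, table
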