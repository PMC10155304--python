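"""Pairwise patient-cluster outcome comparison and cohort summaries.

Continuous outcomes are compared between each unordered pair of patient
clusters with the Mann-Whitney rank-sum test (exact enumeration for
small tie-free samples, tie- and continuity-corrected normal
approximation otherwise); dichotomous outcomes use Fisher's exact test
on the 2x2 event table (two-sided by the point-probability rule).
Within each outcome, p-values across all cluster pairs form one family
and are adjusted by Holm's step-down procedure to control the
familywise error rate.

Missing outcome values are excluded pairwise, so each outcome carries
its own denominators, and pooled summaries aggregate per-cluster cells
by size-weighted means and summed counts.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "rank_sum_test",
    "signed_rank_test",
    "fisher_exact_2x2",
    "holm_adjust",
    "pairwise_compare",
    "cluster_summary",
    "pooled_summary",
    "phenotype_profile",
]

_EXACT_N = 12  # exact rank-sum enumeration up to this pooled sample size


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks for ties.

    The exact null distribution is used when the pooled sample size is
    at most 12 and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    Returns ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_test needs at least one non-missing value per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples (utility; the
    pipeline's cluster comparisons are between independent groups and
    use :func:`rank_sum_test`)."""
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p by hypergeometric enumeration with the
    point-probability rule (all tables at fixed margins whose
    probability does not exceed the observed table's).  The statistic
    is the sample odds ratio ``ad / bc`` (infinite when ``bc = 0``).
    """
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ValueError(f"cell counts must be nonnegative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValueError("empty 2x2 table")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down familywise adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce a
    running maximum so the adjusted values are monotone in the raw
    ordering, cap at 1, and return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pairwise_compare(
    labels: pd.Series,
    outcomes: pd.DataFrame,
    outcome_spec: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs cluster comparison for every outcome (Holm-adjusted
    within each outcome family).

    ``labels`` maps patient_id -> cluster label; ``outcomes`` is
    indexed or keyed by patient_id with one column per outcome;
    ``outcome_spec`` marks each outcome ``"continuous"`` (rank-sum) or
    ``"categorical"`` (Fisher on event/non-event counts).  Pairs where
    one cluster has no non-missing values are marked not-computable
    (NaN p-values) and excluded from the Holm family.
    """
    if "patient_id" in outcomes.columns:
        outcomes = outcomes.set_index("patient_id")
    labels = labels.astype(int)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("pairwise comparison needs at least two clusters")
    bad = set(outcome_spec) - set(outcomes.columns)
    if bad:
        raise KeyError(f"outcomes table lacks columns: {sorted(bad)}")

    records = []
    for outcome, kind in outcome_spec.items():
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"outcome {outcome!r}: kind must be continuous|categorical")
        vals = outcomes[outcome]
        fam: list[int] = []  # indices into records for Holm
        for ca, cb in itertools.combinations(clusters, 2):
            va = vals[labels.index[labels == ca]].dropna()
            vb = vals[labels.index[labels == cb]].dropna()
            rec = {
                "outcome": outcome,
                "cluster_a": ca,
                "cluster_b": cb,
                "test": "rank_sum" if kind == "continuous" else "fisher_exact",
                "n_a": len(va),
                "n_b": len(vb),
                "statistic": np.nan,
                "p_raw": np.nan,
                "p_holm": np.nan,
            }
            if len(va) == 0 or len(vb) == 0:
                logger.warning(
                    "outcome %s, clusters %s vs %s: no non-missing values; not computable",
                    outcome, ca, cb,
                )
                records.append(rec)
                continue
            if kind == "continuous":
                stat, p = rank_sum_test(va.to_numpy(), vb.to_numpy())
            else:
                ea, eb = int((va == 1).sum()), int((vb == 1).sum())
                stat, p = fisher_exact_2x2(ea, len(va) - ea, eb, len(vb) - eb)
            rec["statistic"], rec["p_raw"] = stat, p
            fam.append(len(records))
            records.append(rec)
        if fam:
            adj = holm_adjust([records[i]["p_raw"] for i in fam])
            for i, p_adj in zip(fam, adj):
                records[i]["p_holm"] = float(p_adj)
    return pd.DataFrame.from_records(records)


def cluster_summary(
    labels: pd.Series,
    outcomes: pd.DataFrame,
    outcome_spec: Mapping[str, str],
) -> pd.DataFrame:
    """Per-cluster summary cells: n, mean and sd for continuous
    outcomes, event count and non-missing denominator for categorical
    ones.  One row per cluster, suitable input for
    :func:`pooled_summary`."""
    if "patient_id" in outcomes.columns:
        outcomes = outcomes.set_index("patient_id")
    rows = []
    for c in sorted(labels.astype(int).unique()):
        members = labels.index[labels == c]
        sub = outcomes.loc[outcomes.index.intersection(members)]
        row: dict[str, float] = {"cluster": c, "n": len(members)}
        for outcome, kind in outcome_spec.items():
            vals = sub[outcome].dropna()
            if kind == "continuous":
                row[f"{outcome}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{outcome}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            else:
                row[f"{outcome}_count"] = int((vals == 1).sum())
                row[f"{outcome}_denom"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_summary(per_cluster: pd.DataFrame) -> pd.Series:
    """Pool per-cluster summary cells into the whole-cohort column.

    Pooled n is the sum of cluster sizes; each ``*_mean`` column pools
    as the size-weighted mean of cluster means; each ``*_count`` pools
    as the summed count with its ``*_denom`` summed alongside, and a
    ``*_pct`` percentage is derived from the pooled count and
    denominator (counts without an explicit denominator use the cluster
    sizes).  Means and percentages are reported rounded to one decimal.
    """
    if len(per_cluster) == 0:
        raise ValueError("need at least one cluster row")
    n = per_cluster["n"].to_numpy(dtype=float)
    if (n <= 0).any():
        raise ValueError("cluster sizes must be positive")
    pooled: dict[str, float] = {"n": float(n.sum())}
    for col in per_cluster.columns:
        if col in ("cluster", "n") or col.endswith("_denom") or col.endswith("_sd"):
            continue
        if col.endswith("_mean"):
            vals = per_cluster[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing cell in column {col}")
            pooled[col] = round(float((n * vals).sum() / n.sum()), 1)
        elif col.endswith("_count"):
            name = col[: -len("_count")]
            counts = per_cluster[col].to_numpy(dtype=float)
            denom_col = f"{name}_denom"
            if denom_col in per_cluster.columns:
                denoms = per_cluster[denom_col].to_numpy(dtype=float)
                if np.isnan(denoms).any():
                    raise ValueError(f"missing denominator for outcome {name!r}")
            else:
                denoms = n
            pooled[col] = float(counts.sum())
            pooled[f"{name}_denom"] = float(denoms.sum())
            pooled[f"{name}_pct"] = round(100.0 * counts.sum() / denoms.sum(), 1)
    return pd.Series(pooled)


def phenotype_profile(
    assignment,
    annotations: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Descriptive characterization of each pharmacophenotype.

    For every phenotype (1..K and the K+1 bucket) counts the member
    medications carrying each annotation category (e.g. drug class or
    route flags) with percentages over the phenotype size.  Keys with
    no annotation are tallied under ``unannotated``.
    """
    annotations = annotations or {}
    Kp1 = assignment.K + 1
    members: dict[int, list] = {lab: [] for lab in range(1, Kp1 + 1)}
    for key, labs in assignment.membership.items():
        for lab in labs:
            members[lab].append(key)
    rows = []
    for lab in range(1, Kp1 + 1):
        keys = members[lab]
        size = len(keys)
        counts: dict[str, int] = {}
        for key in keys:
            cats = list(annotations.get(key, [])) or ["unannotated"]
            for cat in cats:
                counts[cat] = counts.get(cat, 0) + 1
        for cat in sorted(counts):
            rows.append(
                {
                    "phenotype": lab,
                    "category": cat,
                    "n": counts[cat],
                    "pct": round(100.0 * counts[cat] / size, 1) if size else np.nan,
                    "phenotype_size": size,
                }
            )
        if size == 0:
            rows.append({"phenotype": lab, "category": "unannotated", "n": 0,
                         "pct": np.nan, "phenotype_size": 0})
    return pd.DataFrame(rows)
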