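"""Common-data-model encoding of medication orders.

A drug order is identified by the composite of drug, dose, strength,
formulation and route.  Orders are canonicalized into order keys
(case-folded, whitespace-collapsed, ``|``-joined) and a cohort becomes a
binary patients x order-keys exposure matrix: entry 1 means the patient
received at least one administration of that exact order in the first
24 h.  Unknown or missing fields count as absences, so two orders that
agree on their known fields map to the same key.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KEY_FIELDS",
    "build_order_key",
    "CohortMatrix",
    "encode_matrix",
    "regimen_complexity",
    "read_mar",
    "write_matrix",
    "read_matrix",
    "read_weights",
]

logger = logging.getLogger(__name__)

KEY_FIELDS = ["drug", "dose", "strength", "formulation", "route"]

_WS = re.compile(r"\s+")


def _canon(field: object) -> str:
    if field is None or (isinstance(field, float) and np.isnan(field)):
        return ""
    return _WS.sub(" ", str(field).strip()).casefold()


def build_order_key(
    drug: str,
    dose: str = "",
    strength: str = "",
    formulation: str = "",
    route: str = "",
) -> str:
    """Canonical composite key ``drug|dose|strength|formulation|route``.

    Case and internal whitespace are normalized so that free-text EHR
    variants of the same order collapse to one key.  The drug name must
    be nonempty.
    """
    drug_c = _canon(drug)
    if not drug_c:
        raise ValueError("order has an empty drug name")
    return "|".join([drug_c, _canon(dose), _canon(strength), _canon(formulation), _canon(route)])


def _keys_for_frame(mar: pd.DataFrame) -> pd.Series:
    cols = {}
    for f in KEY_FIELDS:
        if f in mar.columns:
            cols[f] = mar[f].map(_canon)
        else:
            cols[f] = pd.Series("", index=mar.index)
    if (cols["drug"] == "").any():
        bad = int((cols["drug"] == "").sum())
        raise ValueError(f"{bad} order rows have an empty drug name")
    return cols["drug"].str.cat([cols[f] for f in KEY_FIELDS[1:]], sep="|")


@dataclass
class CohortMatrix:
    """Binary exposure matrix with stable row/column identities.

    Rows are patients (sorted by id), columns are canonical order keys
    in lexicographic order, so the same MAR always yields the same
    matrix regardless of input row order.
    """

    patients: list[str]
    order_keys: list[str]
    X: np.ndarray  # (P, M) uint8 in {0, 1}

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.patients, name="patient_id"),
                            columns=self.order_keys)

    def to_long(self) -> pd.DataFrame:
        """Sparse triplet form: one row per (patient, order_key) exposure."""
        rows, cols = np.nonzero(self.X)
        return pd.DataFrame(
            {
                "patient_id": [self.patients[i] for i in rows],
                "order_key": [self.order_keys[j] for j in cols],
                "exposed": 1,
            }
        )


def encode_matrix(mar: pd.DataFrame, patients: list[str] | None = None) -> CohortMatrix:
    """Encode a long MAR table into a binary exposure matrix.

    Duplicate administrations of the same order collapse to a single
    exposure.  If a ``patients`` roster is given, roster members with
    zero orders are excluded with a logged warning (the matrix only
    carries patients with at least one exposure).  An empty table gives
    a 0 x 0 matrix.
    """
    if len(mar) == 0:
        if patients:
            logger.warning("excluding %d patients with zero orders", len(patients))
        return CohortMatrix([], [], np.zeros((0, 0), dtype=np.uint8))
    keys = _keys_for_frame(mar)
    pids = mar["patient_id"].astype(str)
    if patients is not None:
        present = set(pids)
        missing = [p for p in patients if str(p) not in present]
        if missing:
            logger.warning("excluding %d patients with zero orders", len(missing))
    order_keys = sorted(keys.unique())
    patient_ids = sorted(pids.unique())
    kidx = {k: j for j, k in enumerate(order_keys)}
    pidx = {p: i for i, p in enumerate(patient_ids)}
    X = np.zeros((len(patient_ids), len(order_keys)), dtype=np.uint8)
    X[pids.map(pidx).to_numpy(), keys.map(kidx).to_numpy()] = 1
    return CohortMatrix(patient_ids, order_keys, X)


def regimen_complexity(matrix: CohortMatrix, weights: Mapping[str, float]) -> pd.Series:
    """Weighted regimen-complexity score per patient.

    ``score_i = sum_m X[i, m] * w(m)`` over the supplied order-key
    weights; keys without a weight contribute 0 (their count is
    logged).  This is a generic hook for published complexity scores
    such as the MRC-ICU, whose weight tables are supplied by the user.
    """
    w = np.zeros(len(matrix.order_keys))
    missing = 0
    for j, k in enumerate(matrix.order_keys):
        if k in weights:
            val = float(weights[k])
            if val < 0:
                raise ValueError(f"negative weight for order key {k!r}")
            w[j] = val
        else:
            missing += 1
    if missing:
        logger.info("regimen_complexity: %d order keys without a weight (count as 0)", missing)
    scores = matrix.X.astype(float) @ w
    return pd.Series(scores, index=pd.Index(matrix.patients, name="patient_id"), name="complexity")


# ---------------------------------------------------------------------------
# I/O helpers


def read_mar(path: str | os.PathLike) -> pd.DataFrame:
    """Read a MAR CSV; key fields are kept as strings with empty cells
    (missing counts as absence in the key)."""
    mar = pd.read_csv(path, dtype={f: str for f in KEY_FIELDS} | {"patient_id": str},
                      keep_default_na=False)
    if "admin_time_h" in mar.columns and len(mar):
        mar["admin_time_h"] = pd.to_numeric(mar["admin_time_h"], errors="coerce")
    return mar


def write_matrix(matrix: CohortMatrix, path: str | os.PathLike) -> None:
    """Dense TSV: patients x canonical order keys."""
    matrix.to_frame().to_csv(path, sep="\t")


def read_matrix(path: str | os.PathLike) -> CohortMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CohortMatrix(
        [str(p) for p in df.index], [str(c) for c in df.columns],
        df.to_numpy().astype(np.uint8),
    )


def read_weights(path: str | os.PathLike) -> dict[str, float]:
    """Two-column CSV ``order_key,weight`` -> mapping."""
    df = pd.read_csv(path, dtype={"order_key": str})
    return dict(zip(df["order_key"], df["weight"].astype(float)))
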