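"""Synthetic ICU medication-administration-record (MAR) cohorts.

Generates long-format medication order tables with planted structure:
medications belong to latent co-prescription groups, patients belong to
archetypes that mix over those groups, and outcomes depend on the
archetype.  Every downstream stage of the pharmacophenotyping pipeline
(exposure encoding, RBM feature learning, patient clustering, outcome
comparison) can therefore be tested against known ground truth.

The generative model, per patient:

1. draw an archetype uniformly;
2. draw an order count ``n_i = max(1, Poisson(orders_per_patient_mean))``;
3. for each order, draw a medication group from the archetype's mixing
   row, then a medication uniformly within that group; with probability
   ``noise_rate`` replace the medication with a uniformly random one;
4. draw continuous outcomes from per-archetype normal distributions and
   categorical outcomes from per-archetype Bernoulli probabilities.

Each patient consumes an independent child of the master seed sequence,
so per-patient records are reproducible regardless of cohort size or the
order in which patients are generated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "default_mixing",
    "default_outcome_effects",
    "generate_formulary",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

MAR_COLUMNS = [
    "patient_id",
    "drug",
    "dose",
    "strength",
    "formulation",
    "route",
    "admin_time_h",
]

_ROUTES = ["iv", "po", "ivpb", "subq", "neb"]
_FORMULATIONS = ["soln", "tab", "bag", "inj", "susp"]

# Archetype-level outcome profiles loosely modelled on a mixed
# medical/surgical adult ICU population: severity scores, lengths of
# stay and support durations in days, and event probabilities for
# dichotomous complications.  Continuous outcomes are (per-archetype
# means, shared sd); categorical outcomes are per-archetype event
# probabilities.
_DEFAULT_CONTINUOUS = {
    "apache_ii": ([13.5, 15.7, 14.6, 13.3, 14.7], 6.4),
    "mrc_icu": ([9.4, 11.6, 10.0, 10.1, 11.2], 7.7),
    "icu_los_days": ([6.2, 5.6, 4.7, 4.3, 3.6], 9.0),
    "vasopressor_days": ([2.1, 1.4, 1.5, 2.1, 1.2], 1.4),
}
_DEFAULT_CATEGORICAL = {
    "mortality": [0.099, 0.058, 0.118, 0.132, 0.081],
    "aki": [0.172, 0.115, 0.175, 0.181, 0.115],
    "delirium": [0.356, 0.298, 0.359, 0.238, 0.310],
    "mech_vent": [0.299, 0.435, 0.262, 0.257, 0.333],
}


def default_mixing(n_archetypes: int, n_groups: int, diagonal: float = 0.8) -> np.ndarray:
    """Diagonal-dominant mixing matrix: archetype a puts ``diagonal`` mass
    on group ``a % n_groups`` and spreads the rest evenly."""
    if not 0.0 <= diagonal <= 1.0:
        raise ValueError(f"diagonal weight must be in [0, 1], got {diagonal}")
    if n_groups == 1:
        return np.ones((n_archetypes, 1))
    off = (1.0 - diagonal) / (n_groups - 1)
    mix = np.full((n_archetypes, n_groups), off)
    for a in range(n_archetypes):
        mix[a, a % n_groups] = diagonal
    return mix


def _cycle(values, n):
    return [values[i % len(values)] for i in range(n)]


def default_outcome_effects(n_archetypes: int) -> dict:
    """Per-archetype outcome parameters; profiles are cycled if the
    archetype count differs from the five built-in profiles."""
    return {
        "continuous": {
            name: (_cycle(means, n_archetypes), sd)
            for name, (means, sd) in _DEFAULT_CONTINUOUS.items()
        },
        "categorical": {
            name: _cycle(probs, n_archetypes)
            for name, probs in _DEFAULT_CATEGORICAL.items()
        },
    }


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults describe the "standard" benchmark cohort used throughout
    the test suite: 500 patients, 100 medications in 5 planted groups,
    5 patient archetypes with diagonal-dominant (0.8) mixing, a mean of
    30 orders per patient (roughly the per-patient order volume of a
    real first-24-h ICU MAR) and 5% order noise.
    """

    n_patients: int = 500
    n_medications: int = 100
    n_groups: int = 5
    n_archetypes: int = 5
    mixing: np.ndarray | None = None
    orders_per_patient_mean: float = 30.0
    noise_rate: float = 0.05
    outcome_effects: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_medications < 1:
            raise ValueError("n_medications must be >= 1")
        if self.n_groups < 1 or self.n_groups > self.n_medications:
            raise ValueError(
                f"n_groups must be in [1, n_medications], got {self.n_groups} "
                f"with {self.n_medications} medications"
            )
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if self.orders_per_patient_mean <= 0:
            raise ValueError("orders_per_patient_mean must be > 0")
        if self.mixing is None:
            self.mixing = default_mixing(self.n_archetypes, self.n_groups)
        else:
            mix = np.asarray(self.mixing, dtype=float)
            if mix.shape != (self.n_archetypes, self.n_groups):
                raise ValueError(
                    f"mixing must have shape ({self.n_archetypes}, {self.n_groups}), "
                    f"got {mix.shape}"
                )
            if (mix < 0).any():
                raise ValueError("mixing weights must be nonnegative")
            rowsums = mix.sum(axis=1)
            if (rowsums <= 0).any():
                raise ValueError("each mixing row needs positive total weight")
            self.mixing = mix / rowsums[:, None]
        if self.outcome_effects is None:
            self.outcome_effects = default_outcome_effects(self.n_archetypes)


@dataclass
class SyntheticCohort:
    """A generated cohort: long MAR table, outcome table, and the
    planted truth labels for medications and patients."""

    mar: pd.DataFrame
    outcomes: pd.DataFrame
    truth_med_groups: pd.Series  # order_key -> group label (int)
    truth_archetypes: pd.Series  # patient_id -> archetype label (int)


def generate_formulary(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Build ``n_medications`` distinct order records and their planted
    group labels (round-robin, so group sizes differ by at most one).

    Returns ``(formulary, truth_med_groups)`` where the formulary has
    one row per medication with the five order-key fields and the truth
    series maps the canonical order key to its group.
    """
    from .cdm_encoding import build_order_key

    n, g = spec.n_medications, spec.n_groups
    rows = []
    for i in range(n):
        rows.append(
            {
                "drug": f"drug{i:04d}",
                "dose": f"{(i % 8 + 1) * 25} mg",
                "strength": f"{(i % 4 + 1)} mg/ml" if i % 3 == 0 else "",
                "formulation": _FORMULATIONS[i % len(_FORMULATIONS)],
                "route": _ROUTES[i % len(_ROUTES)],
            }
        )
    formulary = pd.DataFrame(rows)
    keys = [
        build_order_key(r["drug"], r["dose"], r["strength"], r["formulation"], r["route"])
        for r in rows
    ]
    if len(set(keys)) != n:
        raise RuntimeError("formulary produced non-unique order keys")
    groups = pd.Series([i % g for i in range(n)], index=pd.Index(keys, name="order_key"), name="group")
    return formulary, groups


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``spec`` (see module docstring
    for the generative model).  Fully reproducible from ``spec.seed``."""
    formulary, truth_groups = generate_formulary(spec)
    group_members = [
        np.flatnonzero(np.arange(spec.n_medications) % spec.n_groups == g)
        for g in range(spec.n_groups)
    ]

    master = np.random.SeedSequence(spec.seed)
    arch_ss, outcome_ss, patients_ss = master.spawn(3)
    arch_rng = np.random.default_rng(arch_ss)
    outcome_rng = np.random.default_rng(outcome_ss)

    patient_ids = [f"P{i:05d}" for i in range(spec.n_patients)]
    archetypes = arch_rng.integers(0, spec.n_archetypes, size=spec.n_patients)

    mar_rows: list[dict] = []
    per_patient_ss = patients_ss.spawn(spec.n_patients) if spec.n_patients else []
    for i, pid in enumerate(patient_ids):
        rng = np.random.default_rng(per_patient_ss[i])
        a = archetypes[i]
        n_orders = max(1, int(rng.poisson(spec.orders_per_patient_mean)))
        for _ in range(n_orders):
            g = rng.choice(spec.n_groups, p=spec.mixing[a])
            m = int(rng.choice(group_members[g]))
            if rng.random() < spec.noise_rate:
                m = int(rng.integers(spec.n_medications))
            row = formulary.iloc[m].to_dict()
            row["patient_id"] = pid
            row["admin_time_h"] = round(float(rng.uniform(0.0, 24.0)), 3)
            mar_rows.append(row)
    mar = pd.DataFrame(mar_rows, columns=MAR_COLUMNS)

    out = {"patient_id": patient_ids}
    effects = spec.outcome_effects
    for name, (means, sd) in effects.get("continuous", {}).items():
        means = np.asarray(means, dtype=float)
        out[name] = np.round(outcome_rng.normal(means[archetypes], sd), 4)
    for name, probs in effects.get("categorical", {}).items():
        probs = np.asarray(probs, dtype=float)
        out[name] = (outcome_rng.random(spec.n_patients) < probs[archetypes]).astype(int)
    outcomes = pd.DataFrame(out)

    truth_arch = pd.Series(
        archetypes, index=pd.Index(patient_ids, name="patient_id"), name="archetype"
    )
    return SyntheticCohort(mar, outcomes, truth_groups, truth_arch)


def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> dict[str, str]:
    """Write ``mar.csv``, ``outcomes.csv`` and ``truth.csv`` under
    ``directory`` and return the paths.  Empty cohorts produce
    header-only files."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "mar": os.path.join(directory, "mar.csv"),
        "outcomes": os.path.join(directory, "outcomes.csv"),
        "truth": os.path.join(directory, "truth.csv"),
    }
    cohort.mar.to_csv(paths["mar"], index=False)
    cohort.outcomes.to_csv(paths["outcomes"], index=False)
    med = pd.DataFrame(
        {
            "entity_type": "medication",
            "key": cohort.truth_med_groups.index,
            "label": cohort.truth_med_groups.values,
        }
    )
    pat = pd.DataFrame(
        {
            "entity_type": "patient",
            "key": cohort.truth_archetypes.index,
            "label": cohort.truth_archetypes.values,
        }
    )
    pd.concat([med, pat], ignore_index=True).to_csv(paths["truth"], index=False)
    return paths


def read_cohort(directory: str | os.PathLike) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    mar = pd.read_csv(
        os.path.join(directory, "mar.csv"),
        dtype={c: str for c in MAR_COLUMNS if c != "admin_time_h"},
        keep_default_na=False,
    )
    if len(mar):
        mar["admin_time_h"] = mar["admin_time_h"].astype(float)
    outcomes = pd.read_csv(os.path.join(directory, "outcomes.csv"))
    if "patient_id" in outcomes.columns:
        outcomes["patient_id"] = outcomes["patient_id"].astype(str)
    truth = pd.read_csv(os.path.join(directory, "truth.csv"), dtype={"key": str})
    med = truth[truth["entity_type"] == "medication"]
    pat = truth[truth["entity_type"] == "patient"]
    truth_groups = pd.Series(
        med["label"].astype(int).values, index=pd.Index(med["key"], name="order_key"), name="group"
    )
    truth_arch = pd.Series(
        pat["label"].astype(int).values,
        index=pd.Index(pat["key"], name="patient_id"),
        name="archetype",
    )
    return SyntheticCohort(mar, outcomes, truth_groups, truth_arch)
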