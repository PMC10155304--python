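"""End-to-end pharmacophenotyping pipeline.

Orchestrates simulate -> encode -> reduce -> train RBM -> assign
medications -> phenotype distributions -> patient clustering -> outcome
comparison -> report, writing every stage's interface file into a run
directory.  A single master seed deterministically derives per-stage
seeds, so identical configurations produce byte-identical numeric
outputs and individual stages can be re-run in isolation.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from . import cdm_encoding, dim_reduction, outcome_stats, patient_clustering, rbm_phenotyping
from .synthetic_cohort import (
    SyntheticSpec,
    default_mixing,
    generate_cohort,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "radar_table", "write_config", "read_config"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable to a flat
    ``key: value`` text file written next to each run's outputs."""

    out_dir: str = "run"
    input_dir: str | None = None        # existing cohort dir; None -> simulate
    simulate: bool = True
    n_patients: int = 500
    n_medications: int = 100
    n_groups: int = 5
    n_archetypes: int = 5
    mixing_diagonal: float = 0.8
    orders_per_patient_mean: float = 30.0
    noise_rate: float = 0.05
    variance_target: float = 0.70
    max_components: int = 150
    hidden_units: int = 5
    epochs: int = 5000
    learning_rate: float = 0.05
    cd_steps: int = 1
    batch_size: int = 32
    tau: float = 0.5
    exclusive_assignment: bool = False
    distribution_mode: str = "fractional"
    cluster_features: str = "distributions"   # or "pca_scores"
    linkage: str = "ward"
    n_clusters: int | str = 5                 # int or "auto"
    k_max: int = 10
    alpha: float = 0.05
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        order = ["simulate", "rbm"]
        ss = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(ss[order.index(stage)].generate_state(1)[0] % (2**31))


def write_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"{key}: {val}\n")


def read_config(path: str | os.PathLike) -> PipelineConfig:
    fields = {f.name: f.type for f in PipelineConfig.__dataclass_fields__.values()}
    kwargs: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise KeyError(f"unknown config key {key!r}")
            default = getattr(PipelineConfig, key, None)
            if raw == "None":
                kwargs[key] = None
            elif isinstance(default, bool):
                kwargs[key] = raw == "True"
            elif key == "n_clusters":
                kwargs[key] = raw if raw == "auto" else int(raw)
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
    return PipelineConfig(**kwargs)


def radar_table(labels: pd.Series, distributions: pd.DataFrame) -> pd.DataFrame:
    """Mean phenotype distribution per patient cluster (radar-chart
    table): one row per cluster, one column per phenotype.  In
    fractional mode every row is itself a probability vector."""
    cols = [c for c in distributions.columns if c.startswith("phenotype_")]
    missing = labels.index.difference(distributions.index)
    if len(missing):
        raise KeyError(f"labels cover patients absent from distributions: {list(missing)[:3]}")
    df = distributions.loc[labels.index, cols].copy()
    df["cluster"] = labels.values
    out = df.groupby("cluster").mean().sort_index()
    empty = set(labels.unique()) - set(out.index)
    if empty:
        logger.warning("clusters with no members: %s", sorted(empty))
    return out


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write its artifacts under ``config.out_dir``.

    Returns the in-memory stage products (cohort, matrix, models,
    labels, tables) keyed by stage name.  Identical config (including
    seed) produces byte-identical numeric outputs.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    log_path = os.path.join(out, "run.log")
    t0 = time.time()
    stages: dict[str, object] = {}

    def log(msg: str) -> None:
        line = f"[{time.time() - t0:8.2f}s] {msg}"
        logger.info(msg)
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    with open(log_path, "w") as fh:
        fh.write("pharmacophenotyping pipeline run\n")
    write_config(config, os.path.join(out, "run_config.txt"))

    # -- stage: cohort -----------------------------------------------------
    if config.input_dir is not None:
        cohort = read_cohort(config.input_dir)
        log(f"loaded cohort from {config.input_dir}: {len(cohort.mar)} orders")
    elif config.simulate:
        spec = SyntheticSpec(
            n_patients=config.n_patients,
            n_medications=config.n_medications,
            n_groups=config.n_groups,
            n_archetypes=config.n_archetypes,
            mixing=default_mixing(
                config.n_archetypes, config.n_groups, config.mixing_diagonal
            ),
            orders_per_patient_mean=config.orders_per_patient_mean,
            noise_rate=config.noise_rate,
            seed=config.stage_seed("simulate"),
        )
        cohort = generate_cohort(spec)
        write_cohort(cohort, out)
        log(f"simulated cohort: {spec.n_patients} patients, {len(cohort.mar)} orders")
    else:
        raise ValueError("either input_dir must be set or simulate enabled")
    stages["cohort"] = cohort

    # -- stage: encode -----------------------------------------------------
    matrix = cdm_encoding.encode_matrix(cohort.mar)
    cdm_encoding.write_matrix(matrix, os.path.join(out, "matrix.tsv"))
    log(f"encoded exposure matrix {matrix.shape[0]} x {matrix.shape[1]}")
    stages["matrix"] = matrix

    # -- stage: reduce -----------------------------------------------------
    pca = dim_reduction.fit_pca(matrix.X, config.variance_target, config.max_components)
    pca.to_json(os.path.join(out, "pca_model.json"))
    scores = dim_reduction.transform(pca, matrix.X)
    _write_tsv(
        pd.DataFrame(scores, index=pd.Index(matrix.patients, name="patient_id"),
                     columns=[f"pc{i + 1}" for i in range(pca.n_components)]),
        os.path.join(out, "pca_scores.tsv"),
    )
    log(f"PCA: {pca.n_components} components, "
        f"{pca.explained_variance_ratio.sum():.3f} variance retained")
    stages["pca"] = pca

    # -- stage: train + assign --------------------------------------------
    model = rbm_phenotyping.train_rbm(
        matrix.X,
        K=config.hidden_units,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        cd_steps=config.cd_steps,
        batch_size=config.batch_size,
        seed=config.stage_seed("rbm"),
        feature_names=matrix.order_keys,
    )
    model.to_json(os.path.join(out, "rbm_model.json"))
    assignment = rbm_phenotyping.assign_medications(
        model, tau=config.tau, exclusive=config.exclusive_assignment
    )
    assignment.to_frame().to_csv(os.path.join(out, "assignment.csv"), index=False)
    n_unassigned = sum(
        1 for s in assignment.membership.values() if assignment.unassigned_label in s
    )
    log(f"RBM trained ({config.epochs} epochs); {model.M - n_unassigned} medications "
        f"assigned to {config.hidden_units} phenotypes, {n_unassigned} unassigned")
    stages["rbm"] = model
    stages["assignment"] = assignment

    # -- stage: distribute -------------------------------------------------
    dist = patient_clustering.phenotype_distribution(
        matrix, assignment, mode=config.distribution_mode
    )
    _write_tsv(dist, os.path.join(out, "distributions.tsv"))
    stages["distributions"] = dist

    # -- stage: cluster ----------------------------------------------------
    if config.cluster_features == "pca_scores":
        features = scores
    else:
        features = patient_clustering.distribution_features(dist)
    tree = patient_clustering.hac(features, linkage=config.linkage)
    np.savetxt(os.path.join(out, "linkage.txt"), tree.Z, fmt=_FLOAT_FMT)
    if config.n_clusters == "auto":
        k, gap_table = patient_clustering.suggest_k(tree, k_max=config.k_max)
        _write_tsv(gap_table, os.path.join(out, "gap_table.tsv"), index=False)
        log(f"suggest_k chose k={k}")
    else:
        k = int(config.n_clusters)
    label_arr = patient_clustering.cut_tree(tree, k)
    labels = pd.Series(label_arr, index=dist.index, name="cluster")
    labels.to_frame().to_csv(os.path.join(out, "labels.csv"))
    log(f"patients clustered into {k} clusters "
        f"(sizes {labels.value_counts().sort_index().tolist()})")
    stages["tree"] = tree
    stages["labels"] = labels

    # -- stage: compare ----------------------------------------------------
    outcome_spec = _infer_outcome_spec(cohort.outcomes)
    if labels.nunique() >= 2:
        comparisons = outcome_stats.pairwise_compare(
            labels, cohort.outcomes, outcome_spec, alpha=config.alpha
        )
    else:
        log("only one effective patient cluster; pairwise comparisons skipped")
        comparisons = pd.DataFrame(
            columns=["outcome", "cluster_a", "cluster_b", "test",
                     "n_a", "n_b", "statistic", "p_raw", "p_holm"]
        )
    _write_tsv(comparisons, os.path.join(out, "comparisons.tsv"), index=False)
    summary = outcome_stats.cluster_summary(labels, cohort.outcomes, outcome_spec)
    pooled = outcome_stats.pooled_summary(summary)
    _write_tsv(summary, os.path.join(out, "summary.tsv"), index=False)
    _write_tsv(pooled.to_frame("pooled"), os.path.join(out, "summary_pooled.tsv"))
    profile = outcome_stats.phenotype_profile(assignment)
    _write_tsv(profile, os.path.join(out, "profile.tsv"), index=False)
    stages["comparisons"] = comparisons
    stages["summary"] = summary

    # -- stage: report -----------------------------------------------------
    radar = radar_table(labels, dist)
    _write_tsv(radar, os.path.join(out, "radar.csv"))
    stages["radar"] = radar
    sig = comparisons[comparisons["p_holm"] < config.alpha]
    log(f"pairwise comparisons: {len(comparisons)} tests, "
        f"{len(sig)} significant after Holm at alpha={config.alpha}")
    log("done")
    return stages


def _infer_outcome_spec(outcomes: pd.DataFrame) -> dict[str, str]:
    """Outcomes with only {0, 1, NaN} values are categorical, the rest
    continuous."""
    spec: dict[str, str] = {}
    for col in outcomes.columns:
        if col == "patient_id":
            continue
        vals = outcomes[col].dropna().unique()
        spec[col] = "categorical" if np.isin(vals, (0, 1)).all() else "continuous"
    return spec
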