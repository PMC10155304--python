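#!/usr/bin/env python
"""Compare outcomes between patient clusters.

Runs every pairwise cluster comparison (rank-sum for continuous
outcomes, Fisher's exact for dichotomous ones, Holm adjustment within
each outcome), writes the comparison and summary tables, and builds
the per-cluster mean phenotype distribution (radar-chart table).
"""

import pandas as pd

from pharmphen.outcome_stats import cluster_summary, pairwise_compare, pooled_summary
from pharmphen.pipeline import _infer_outcome_spec, radar_table

OUT = "results"


def main() -> None:
    labels = pd.read_csv(f"{OUT}/labels.csv", index_col=0)["cluster"]
    outcomes = pd.read_csv(f"{OUT}/cohort/outcomes.csv")
    dist = pd.read_csv(f"{OUT}/distributions.tsv", sep="\t", index_col=0)

    spec = _infer_outcome_spec(outcomes)
    comparisons = pairwise_compare(labels, outcomes, spec)
    comparisons.to_csv(f"{OUT}/comparisons.csv", index=False, float_format="%.6g")
    sig = comparisons[comparisons["p_holm"] < 0.05]
    print(f"{len(comparisons)} pairwise tests over {len(spec)} outcomes; "
          f"{len(sig)} significant after Holm at alpha = 0.05")
    if len(sig):
        print(sig[["outcome", "cluster_a", "cluster_b", "p_raw", "p_holm"]]
              .to_string(index=False))

    summary = cluster_summary(labels, outcomes, spec)
    summary.to_csv(f"{OUT}/summary_by_cluster.csv", index=False, float_format="%.6g")
    pooled = pooled_summary(summary)
    pooled.to_frame("pooled").to_csv(f"{OUT}/summary_pooled.csv", float_format="%.6g")
    print(f"per-cluster summary in {OUT}/summary_by_cluster.csv; pooled column in "
          f"{OUT}/summary_pooled.csv")

    radar = radar_table(labels, dist)
    radar.to_csv(f"{OUT}/radar.csv", float_format="%.6g")
    print("mean phenotype distribution per cluster (radar table):")
    print(radar.round(3).to_string())


if __name__ == "__main__":
    main()
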