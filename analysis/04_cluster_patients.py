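#!/usr/bin/env python
"""Cluster patients on their normalized phenotype distributions.

Builds each patient's normalized pharmacophenotype distribution from
the exposure matrix and the medication assignment, runs Ward
hierarchical agglomerative clustering, checks the dendrogram-gap
heuristic against the configured k = 5, and scores the cut against the
planted archetypes.
"""

import numpy as np
import pandas as pd

from pharmphen.cdm_encoding import read_matrix
from pharmphen.patient_clustering import (
    cut_tree,
    distribution_features,
    hac,
    phenotype_distribution,
    suggest_k,
)
from pharmphen.rbm_phenotyping import RBMModel, assign_medications
from pharmphen.synthetic_cohort import read_cohort

OUT = "results"


def main() -> None:
    matrix = read_matrix(f"{OUT}/exposure_matrix.tsv")
    cohort = read_cohort(f"{OUT}/cohort")
    model = RBMModel.from_json(f"{OUT}/rbm_model.json")

    assignment = assign_medications(model, tau=0.5)
    dist = phenotype_distribution(matrix, assignment, mode="fractional")
    dist.to_csv(f"{OUT}/distributions.tsv", sep="\t", float_format="%.10g")

    tree = hac(distribution_features(dist), linkage="ward")
    np.savetxt(f"{OUT}/linkage.txt", tree.Z, fmt="%.10g")
    k_hat, gaps = suggest_k(tree, k_max=10)
    gaps.to_csv(f"{OUT}/gap_table.csv", index=False, float_format="%.6g")
    print(f"dendrogram-gap heuristic suggests k = {k_hat} "
          f"(gap table in {OUT}/gap_table.csv)")

    labels = pd.Series(cut_tree(tree, 5), index=dist.index, name="cluster")
    labels.to_frame().to_csv(f"{OUT}/labels.csv")
    print("cluster sizes:", labels.value_counts().sort_index().to_dict())

    truth = cohort.truth_archetypes.loc[dist.index]
    ct = pd.crosstab(truth, labels)
    ct.to_csv(f"{OUT}/clusters_vs_truth.csv")
    from math import comb

    t = ct.to_numpy()
    n = t.sum()
    sij = sum(comb(v, 2) for v in t.ravel())
    sa = sum(comb(v, 2) for v in t.sum(1))
    sb = sum(comb(v, 2) for v in t.sum(0))
    exp = sa * sb / comb(n, 2)
    ari = (sij - exp) / ((sa + sb) / 2 - exp)
    print(f"patient clusters vs planted archetypes: ARI {ari:.3f} "
          f"(contingency table in {OUT}/clusters_vs_truth.csv)")


if __name__ == "__main__":
    main()
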