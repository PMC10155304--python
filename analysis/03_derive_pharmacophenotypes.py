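#!/usr/bin/env python
"""Train the RBM and assign medications to pharmacophenotypes.

Fits the 5-hidden-unit Bernoulli RBM (5000 epochs, centered CD-1 with
a 1/K sparsity target) on the exposure matrix, derives the medication
-> pharmacophenotype assignment from each medication's hidden-unit
activation pattern, and scores the assignment against the planted
medication groups.
"""

import numpy as np
import pandas as pd

from pharmphen.cdm_encoding import read_matrix
from pharmphen.rbm_phenotyping import assign_medications, train_rbm
from pharmphen.synthetic_cohort import read_cohort

OUT = "results"


def main() -> None:
    matrix = read_matrix(f"{OUT}/exposure_matrix.tsv")
    cohort = read_cohort(f"{OUT}/cohort")

    model = train_rbm(matrix.X, K=5, epochs=5000, seed=7,
                      feature_names=matrix.order_keys)
    model.to_json(f"{OUT}/rbm_model.json")
    trace = np.array([p for _, p in model.training_trace])
    h = len(trace) // 2
    print(f"RBM trained: pseudo-log-likelihood {trace[0]:.1f} (init) -> "
          f"{trace[-1]:.1f} (final); second-half mean exceeds first-half by "
          f"{trace[h:].mean() - trace[:h].mean():+.2f}")

    assignment = assign_medications(model, tau=0.5)
    assignment.to_frame().to_csv(f"{OUT}/assignment.csv", index=False)
    sizes = assignment.to_frame()["phenotype"].value_counts().sort_index()
    n_unassigned = sizes.get(assignment.unassigned_label, 0)
    print(f"pharmacophenotype sizes (6 = unassigned bucket): {sizes.to_dict()}")
    print(f"{matrix.shape[1] - n_unassigned} medications assigned, "
          f"{n_unassigned} unassigned")

    exclusive = assign_medications(model, exclusive=True).labels()
    pred = [exclusive[k] for k in matrix.order_keys]
    truth = [cohort.truth_med_groups[k] for k in matrix.order_keys]
    ct = pd.crosstab(pd.Series(truth, name="planted_group"),
                     pd.Series(pred, name="phenotype"))
    ct.to_csv(f"{OUT}/assignment_vs_truth.csv")
    from math import comb

    def ari(x, y):
        t = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
        n = t.sum()
        sij = sum(comb(v, 2) for v in t.ravel())
        sa = sum(comb(v, 2) for v in t.sum(1))
        sb = sum(comb(v, 2) for v in t.sum(0))
        exp = sa * sb / comb(n, 2)
        return (sij - exp) / ((sa + sb) / 2 - exp)

    print(f"assignment vs planted groups: ARI {ari(truth, pred):.3f} "
          f"(contingency table in {OUT}/assignment_vs_truth.csv)")


if __name__ == "__main__":
    main()
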