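#!/usr/bin/env python
"""Encode the medication records and inspect the principal components.

Builds the binary patient x order-key exposure matrix from the
simulated MAR, fits PCA with the 70% explained-variance rule, and
reports how many components the rule keeps.
"""

import pandas as pd

from pharmphen.cdm_encoding import encode_matrix, read_mar, write_matrix
from pharmphen.dim_reduction import fit_pca, transform

OUT = "results"


def main() -> None:
    mar = read_mar("results/cohort/mar.csv")
    matrix = encode_matrix(mar)
    write_matrix(matrix, f"{OUT}/exposure_matrix.tsv")
    print(f"exposure matrix: {matrix.shape[0]} patients x {matrix.shape[1]} order keys, "
          f"density {matrix.X.mean():.3f}")

    pca = fit_pca(matrix.X, variance_target=0.70, max_components=150)
    scores = transform(pca, matrix.X)
    pd.DataFrame(
        {"component": range(1, pca.n_components + 1),
         "explained_variance_ratio": pca.explained_variance_ratio},
    ).to_csv(f"{OUT}/pca_variance.csv", index=False)
    print(f"PCA keeps {pca.n_components} components to pass 70% variance "
          f"(cumulative {pca.explained_variance_ratio.sum():.3f}); "
          f"scores shape {scores.shape}")
    print(f"wrote {OUT}/exposure_matrix.tsv and {OUT}/pca_variance.csv")


if __name__ == "__main__":
    main()
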