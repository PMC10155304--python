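#!/usr/bin/env python
"""Worked example: pool a per-cluster demographic table.

Applies the pooled-summary arithmetic to the built-in worked-example
table (five patient clusters from a 991-patient ICU cohort) and prints
the reconstructed whole-cohort column: pooled N, size-weighted means,
and pooled event percentages with their per-outcome denominators.
"""

from pharmphen.example_tables import icu_demographics_example
from pharmphen.outcome_stats import pooled_summary

OUT = "results"


def main() -> None:
    table = icu_demographics_example()
    pooled = pooled_summary(table)
    table.to_csv(f"{OUT}/demographics_by_cluster.csv", index=False)
    pooled.to_frame("pooled").to_csv(f"{OUT}/demographics_pooled.csv")
    print("per-cluster cells (n per cluster):", table["n"].tolist())
    print(f"pooled N = {pooled['n']:.0f}")
    for name in ("age_mean", "apache_ii_mean", "mrc_icu_mean",
                 "vasopressor_days_mean"):
        print(f"pooled {name}: {pooled[name]}")
    for name in ("mortality", "female", "medical_icu", "mech_vent", "aki"):
        print(f"pooled {name}: {pooled[f'{name}_count']:.0f} "
              f"({pooled[f'{name}_pct']}%, denominator "
              f"{pooled[f'{name}_denom']:.0f})")


if __name__ == "__main__":
    main()
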