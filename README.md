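# pharmphen

Unsupervised pharmacophenotyping of ICU medication administration
records (MARs).

Critically ill patients receive dozens of drug orders in their first
24 h, and the combinatorics of those regimens hide patterns no single
clinician can enumerate.  `pharmphen` is for clinical-informatics and
pharmacoepidemiology researchers who want to ask: *which medications
travel together* (pharmacophenotypes), *which patients share regimen
profiles* (patient clusters), and *do those clusters differ in
outcomes* (length of stay, ventilation, mortality, AKI, delirium)?

## The model

Orders are canonicalized into composite keys
(`drug|dose|strength|formulation|route`) and encoded as a binary
exposure matrix `X in {0,1}^(P x M)` (patient received order at least
once in the first 24 h).  A Bernoulli restricted Boltzmann machine with
energy

    E(v, h) = -b·v - c·h - hᵀW v,   p(h_j=1|v) = σ(c_j + W_j·v)

is trained by contrastive divergence (centered gradient, hidden
sparsity target 1/K, 5000 epochs, K = 5 hidden units) on the rows of
`X`.  Each medication m is assigned to every phenotype j whose hidden
unit is on average activated (mean `p(h_j=1|v) > τ = 0.5`) among the
patients who received m; medications activating no unit form the
explicit unassigned bucket K+1.  Each patient is then summarized by
their normalized phenotype distribution (fraction of their distinct
exposures per phenotype), patients are merged by Ward hierarchical
agglomerative clustering, the dendrogram is cut at k clusters (a
relative-gap heuristic stands in for visual inspection), and outcomes
are compared between all cluster pairs with Mann-Whitney rank-sum /
Fisher's exact tests under Holm familywise adjustment per outcome.

A synthetic MAR generator with planted medication groups, patient
archetypes and archetype-dependent outcomes makes every stage testable
without any data access.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
standard synthetic cohort (run them in order; tables land in
`results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_encode_and_reduce.py
python analysis/03_derive_pharmacophenotypes.py
python analysis/04_cluster_patients.py
python analysis/05_compare_outcomes.py
python analysis/06_pooled_demographics.py
```

Output of the core stages (seed 7):

```
cohort: 500 patients, 15165 medication orders, 100 distinct order keys (30.3 orders/patient)
PCA keeps 37 components to pass 70% variance (cumulative 0.707)
RBM trained: pseudo-log-likelihood -50.5 (init) -> -35.2 (final)
pharmacophenotype sizes (6 = unassigned bucket): {1: 20, 2: 20, 3: 20, 4: 20, 5: 20}
assignment vs planted groups: ARI 1.000
dendrogram-gap heuristic suggests k = 5
cluster sizes: {1: 119, 2: 107, 3: 103, 4: 95, 5: 76}
patient clusters vs planted archetypes: ARI 1.000
80 pairwise tests over 8 outcomes; 9 significant after Holm at alpha = 0.05
```

The five planted medication groups are recovered exactly (adjusted
Rand index 1.0 against the planted labels), the gap heuristic picks
the planted cluster count, and the outcome comparisons flag exactly
the outcomes the generator gave real between-archetype spread (APACHE
II and vasopressor days), with the per-cluster mean phenotype
distributions (`results/radar.csv`) showing each cluster dominated by
its own phenotype (~0.67 on the diagonal).

The same machinery pools a per-cluster demographic table into its
whole-cohort column; `analysis/06_pooled_demographics.py` reconstructs,
from five printed cluster cells of a 991-patient ICU cohort, the pooled
N = 991, mean age 61.2, APACHE II 14.3, MRC-ICU 10.3, mortality
97 (9.8%), and the remaining pooled percentages, each exact at
one-decimal reporting precision.

An end-to-end driver is also available as a library call:

```python
from pharmphen.pipeline import PipelineConfig, run_pipeline
stages = run_pipeline(PipelineConfig(out_dir="run", seed=3))
```

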