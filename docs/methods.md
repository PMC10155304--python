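# Methods

`pharmphen` implements a two-level unsupervised pharmacophenotyping
analysis of ICU medication administration records (MARs): medications
are clustered into *pharmacophenotypes* from their co-prescription
structure using a restricted Boltzmann machine (RBM), and patients are
then clustered on their normalized distribution over those
pharmacophenotypes, with nonparametric pairwise outcome comparisons
between the resulting patient clusters.

## Order encoding (common data model)

A drug order is identified by the composite of drug, dose, strength,
formulation and route.  Fields are case-folded, internal whitespace is
collapsed, and the parts are joined with `|` into a canonical *order
key*; unknown or missing fields count as absences (empty string), so
records agreeing on their known fields collapse to one key.  The cohort
becomes a binary matrix `X` (patients x order keys) with `X[i,m] = 1`
iff patient i received order m at least once in the first 24 h.
Duplicate administrations collapse; columns are sorted
lexicographically and rows by patient id so the matrix is invariant to
input row order.  Patients without any order are excluded (with a
logged warning): the analysis is defined on exposure profiles.

A generic regimen-complexity hook computes `score_i = sum_m X[i,m] w(m)`
for a user-supplied nonnegative weight table over order keys
(published complexity scores such as the MRC-ICU can be plugged in;
keys without a weight contribute zero and are counted in the log).

## Dimensionality reduction

PCA is fitted by SVD of the column-centered matrix (indicator columns
share a scale, so no standardization).  The component count is the
smallest n whose cumulative explained-variance ratio strictly exceeds
`variance_target` (default 0.70), capped by `max_components` (default
150) and by the matrix rank.  The sign of each component is fixed by
making its largest-magnitude loading positive, so scores are
reproducible across runs and platforms.  The PCA stage is reported
alongside the pipeline; the RBM itself consumes the binary matrix,
because the medication-to-phenotype assignment needs
medication-indexed visible units.

## RBM pharmacophenotyping

The RBM is a Bernoulli-Bernoulli energy model
`E(v, h) = -b.v - c.h - h.W.v` with M visible units (medications) and
K hidden units (candidate phenotypes, default K = 5).  Conditionals
factorize: `p(h_j=1|v) = sigmoid(c_j + W[j].v)`,
`p(v_m=1|h) = sigmoid(b_m + h.W[:,m])`.  Training is minibatch CD-k
(default k = 1, batch 32, learning rate 0.05, 5000 epochs, weights
initialized Normal(0, 0.01)).

Two standard refinements are on by default, because plain CD proved
unable to keep K hidden units on K distinct co-prescription blocks over
long runs (units go dead or merge two blocks while another block is
absorbed into the visible biases — the entangled solutions actually
score *higher* pseudo-likelihood, so no readout can undo them):

* **Centered gradient.** The weight update is computed on offset
  variables `(v - mu)` and `(h - lambda)`, with `mu` the visible data
  means and `lambda` a running mean of hidden activations, and visible
  biases start at the empirical log-odds.  Bias updates carry the
  matching correction terms (`gb = <v0-vk> - gW'.lambda`,
  `gc = <ph0-phk> - gW.mu`).  This removes the incentive for hidden
  units to model overall exposure density.
* **Sparsity target.** Hidden biases are nudged toward a mean
  activation of `1/K` (strength 0.5) via an exponential running mean of
  the data-clamped activations.  With archetype-structured cohorts a
  selective unit is the right prior: each phenotype should switch on
  for a subset of patients, not for everyone.

`centered=False, sparsity_cost=0` recovers textbook CD-k exactly; the
exhaustive-state oracle tests run in that mode.  Training is fully
reproducible from the seed; the evaluation of the training trace (the
full-coordinate pseudo-log-likelihood, recorded at epoch 0 and every
`eval_interval` epochs) draws nothing from the training RNG stream.
Divergence (non-finite parameters) raises an error naming the epoch.

### Medication assignment

A medication joins every phenotype whose hidden unit it *activates*;
medications activating no unit form the explicit unassigned bucket
K+1.  Two activation statistics are provided:

* **Activation pattern over the cohort (default for fitted models).**
  Unit j claims medication m if the mean of `p(h_j=1|v)` over the
  patients who received m exceeds `tau` (default 0.5, the natural
  decision boundary on the probability scale).  This is recorded in the
  model at fit time, so assignment is a pure function of the trained
  model.
* **One-hot probe** (`method="probe"`): threshold `p(h_j=1|e_m)` on the
  bare one-hot input.  This is the right reading for hand-built or
  uncalibrated models (zero offsets), and the two coincide there; for a
  *calibrated* block detector it is uninformative — a unit that
  integrates ~15 co-occurring medications needs far more than one
  active visible to cross 0.5, so every medication would land in K+1.

Multi-membership is allowed by default (phenotypes may overlap); an
`exclusive` mode keeps only the strongest activation, and is what the
recovery benchmark scores against planted groups (a partition metric
needs one label per medication).  Raising `tau` never grows any
membership set.

## Patient clustering

Each patient's feature vector is the normalized phenotype distribution:
counts of their distinct order keys per phenotype (1..K and K+1)
divided by their total distinct exposures.  In the default *fractional*
mode a key belonging to several phenotypes contributes `1/|membership|`
to each, so the vector is a probability distribution; *full* mode
counts overlaps whole (rows may sum past 1) for fidelity to a literal
reading of per-phenotype counting.

Patients are merged bottom-up by hierarchical agglomerative clustering
— Ward linkage on Euclidean distances by default (the common default of
the toolkit this analysis style is built on), with average, complete
and single linkage available.  The tree is cut at a configured count
(default 5); labels are renumbered 1..C by descending cluster size with
ties broken by lowest member index.  As a programmatic surrogate for
visual dendrogram inspection, `suggest_k` returns the k in [2, k_max]
maximizing the relative merge-height gap
`(h[P-k+1] - h[P-k]) / h[P-k]`, together with the full gap table so a
human can override; an all-equal-heights tree returns k = 2 with a
flat-gap warning.  Clustering PCA scores instead of distributions is
available behind a flag.

## Outcome statistics

All C(C-1)/2 unordered cluster pairs are tested for every outcome:

* **Continuous** outcomes use the two-sided Mann-Whitney rank-sum test
  with midranks for ties — exact enumeration when the pooled sample is
  at most 12 without ties, otherwise the normal approximation with tie
  and continuity corrections.  (A paired signed-rank test is exposed as
  a utility but unused: cluster comparisons are between independent
  groups.)  An all-identical pooled sample returns p = 1.
* **Dichotomous** outcomes use Fisher's exact test on the 2x2
  event/non-event table, two-sided by the point-probability rule (sum
  of all tables at the fixed margins whose probability does not exceed
  the observed one, with a 1e-7 relative slack); the statistic is the
  sample odds ratio ad/bc, infinite when bc = 0.
* **Holm adjustment** is applied within each outcome's family of pairs
  (step-down: sort ascending, multiply the i-th smallest by m-i+1,
  enforce the running maximum, cap at 1).  Missing values are excluded
  pairwise, so every outcome carries its own denominators; a pair where
  one cluster has no non-missing values is marked not computable and
  excluded from its family.

Per-cluster summaries report n, mean and SD for continuous outcomes and
event count plus denominator for dichotomous ones; pooling sums sizes,
counts and denominators and takes size-weighted means, reporting means
and percentages rounded to one decimal.  A phenotype-profile table
counts member medications per annotation category (unannotated keys are
tallied explicitly).

## Synthetic cohorts

The generator emulates the statistical structure this analysis assumes,
with planted ground truth for every stage: medications belong to latent
co-prescription groups (round-robin, sizes within one of each other);
each patient draws an archetype uniformly, an order count
`max(1, Poisson(mean))` (so every patient has a regimen), then orders
by sampling a group from the archetype's mixing row and a medication
uniformly within the group, replaced with a uniform random medication
with probability `noise_rate`; administration times are uniform on
[0, 24) h.  Continuous outcomes are Normal(archetype mean, sd) and
dichotomous outcomes Bernoulli(archetype probability).  One master seed
sequence drives everything, with an independent child stream per
patient, so records are reproducible under re-ordering and cohort
resizing.

Defaults define the standard benchmark: 500 patients, 100 medications,
5 groups, 5 archetypes, mixing 0.8 on the diagonal with the remainder
spread evenly, 30 orders per patient (matching the ~31 orders/patient
scale of real first-24-h ICU MARs), 5% noise.  Outcome profiles mirror
a mixed medical/surgical adult ICU population (APACHE II means ~13–16,
ICU stays of a few days, mortality ~6–13%, etc.).

What the generator does **not** emulate — and hence what passing
recovery tests do and do not show: no pharmacokinetics or dose logic,
no within-stay temporal dynamics (a timestamp column only), outcomes
independent given the archetype, Gaussian outcomes can go negative
(durations are not truncated), and group structure is cleanly blocked
where real formularies overlap heavily.  Recovery of planted structure
shows the pipeline is a consistent estimator of the structure it
assumes, not that real MAR data contains such structure.

## Numerical and design choices

* Tolerances: PCA orthonormality and variance conservation at 1e-8;
  probability-vector checks at 1e-9; oracle agreement for enumerated
  statistics at 1e-10 or better.
* Tie-breaks: lexicographic column order; lowest-index merge ties in
  the naive HAC oracle; stable sort in Holm; size-then-lowest-index
  cluster renumbering.
* Degenerate inputs: empty MAR -> 0x0 matrix; constant matrix -> PCA
  error naming the cause; flat dendrogram -> k = 2 with warning;
  one-cluster labelings skip pairwise comparison with a log line.
* The pipeline derives one sub-seed per stochastic stage (simulation,
  RBM) from the master seed, so stages can be re-run in isolation and
  a full rerun is byte-identical (floats are written with a fixed
  `%.10g` format).
* Problem sizes used by the test suite and the acceptance script —
  five training runs on the standard 500 x 100 cohort, 200 null
  replicates for the familywise-error check, and one full pipeline
  rerun pair — were chosen to exercise the study-scale configuration
  (5000 epochs, K = 5) while keeping a complete run in the minutes
  range on one CPU.

## Known limitations

* K is fixed, not selected; the hidden-unit count is a modeling choice
  as in the underlying analysis style.
* The RBM is a shallow representation; deeply overlapping or
  hierarchical prescription patterns would need richer models.
* Cluster-outcome associations are descriptive; no causal claims are
  supported, and no regression/survival adjustment is provided.
* The one-hot probe and the cohort-activation statistic can disagree on
  calibrated models (by design); users comparing both should expect the
  probe to under-assign.
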