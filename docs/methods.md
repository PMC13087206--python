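# Methods

This note documents the models, estimators and design choices behind
`privcohort`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic study cohort

No real claims data ship with (or are needed by) the package. The
`cohort` module generates a seeded stand-in for a small anticoagulation
cohort: adults with a first venous thromboembolism (VTE) starting either
a DOAC (exposed arm) or a VKA (comparator arm), one row per individual,
39 attributes — 3 demographic, 20 binary comorbidity flags, 9
study-bookkeeping attributes and 7 outcome attributes. Eight flag names
are taken from the emulated study's published figures; the remaining
twelve are explicit stand-ins (`Attribute.standin` records which is
which). `patient_pseudonym` stands in for the hash-based insured-person
pseudonym of a claims extract and is the schema's only direct
identifier.

Generative model, in order:

* **Treatment arm**: Bernoulli(0.715) for the exposed arm — the emulated
  cohort's 71.5/28.5 split.
* **Age**: Normal(74.7, 11.67), rounded, truncated to 18–108.
* **Gender**: per-arm female probabilities (0.445 / 0.405), giving an
  overall female share near 43%.
* **Comorbidity flags**: a latent Gaussian-threshold (Gaussian-copula)
  model. A shared latent vector Z ~ N(0, R) is thresholded per flag at
  the per-arm prevalence quantile, so any positive semi-definite latent
  correlation target R is supported and per-arm prevalences are exact in
  expectation. The default R is exchangeable (0.15) within a
  cardiometabolic cluster and identity elsewhere. Default prevalences
  span common (arterial hypertension ~0.75) to deliberately rare
  (obesity 0.002, i.e. a handful of cases in 1727 records) so that
  protection methods visibly erase rare flags, as happens in practice.
* **Dates**: the first-VTE date is uniform over 2016–2018; the index
  (treatment-start) date follows within 30 days; the birth quarter is
  derived from age. Dates are stored ISO-8601; day offsets are integers
  with offset 0 = the first-VTE date.
* **Outcomes**: per-outcome, per-arm exponential event times (events per
  day), right-censored by an Exponential(0.001) dropout time truncated
  at a 365-day administrative follow-up. Death ends follow-up; bleeding
  and rehospitalization are additionally censored at the death/censor
  time. Default hazards (death 1.25e-4 vs 1.0e-4; bleeding 9.5e-5 vs
  7.6e-5) give a per-arm hazard ratio of 1.25 and expected event counts
  in the tens per arm with fewer comparator events — the rare-event
  regime that makes the downstream utility analysis genuinely hard. The
  1.25 ratio is the recoverable ground truth for the utility stage.

The generator recovers its parameters (prevalences within 3 SE, hazard
MLEs within 10% at n = 50 000 — asserted in the test suite) and is
byte-deterministic given the seed. What it does **not** emulate: ICD/ATC
code-level structure, longitudinal multi-row claims, informative
censoring, missing data, or any real-world dependence between, say,
gender and contraceptive prescriptions. Consequently, passing tests show
that the *pipeline machinery* behaves correctly under controlled
conditions, not that any particular protection method is safe or useful
on real claims data.

## Threat modeling

Attributes are rated 1–3 on replicability (temporal stability),
availability (plausibility of external knowledge) and distinguishability
(ability to single out); the ratings sum to a score in 3–9 compared
against a threshold (≥, by convention) to flag indirect identifiers.
Direct identifiers bypass scoring; remaining attributes whose disclosure
could cause harm are sensitive; the rest are insensitive. Ratings are
expert inputs: the bundled defaults cover the stand-in schema and are
calibrated so that, at the default threshold of 7, the classification
yields 1 direct / 10 indirect / 5 sensitive / 23 insensitive — the
published category counts for this kind of cohort. All three inputs
(ratings, sensitivity marks, threshold) are overridable via YAML.

## Anonymization

**Privacy models.** k-anonymity with k = 2 and equal-distance
t-closeness with t = 0.5. Equal ground distances reduce the earth-mover
distance to total variation, so the t check is
`0.5 · Σ_v |P_class(v) − P_table(v)| ≤ t` per equivalence class; the
checker is exposed separately (`check_t_closeness`) and every
anonymization output is validated against both checkers in the tests.

**Transformations.** Per-attribute hierarchies whose levels strictly
coarsen: ages generalize to 5- or 10-year intervals, day offsets and
durations to 30/90/360-day intervals, categorical and binary attributes
only to full suppression. Numeric generalized cells are represented by
the midpoint of the interval *clipped to the attribute's domain* — the
unclipped midpoint can leave the observed range entirely (offsets 0–30
generalized at width 90 would all become 45) and spuriously destroy
every distance-based fidelity metric. Date attributes (birth quarter,
first-VTE date) are not lattice dimensions: they are microaggregated to
the class-wise mean date (rounded to the day) within the final
equivalence classes. The other date columns travel through protection as
day offsets only and are rebuilt afterwards as anchor + offset midpoint.

**Suppression semantics.** Residual classes smaller than k, and classes
violating t (iterated to a fixpoint, since removing a class shifts the
table distribution), are suppressed entirely; the record-suppression
limit defaults to 100%. Whole-attribute suppression is the hierarchy's
top level, and suppressing a binary flag for all records equals removing
the attribute. Per-cell suppression is not searched: the configuration
accepts the flag for interface compatibility, but the search space is
attribute-level — the situation per-cell suppression would address (a
top level forced for a whole attribute) is exactly what attribute
suppression expresses.

**Objective and search.** Granularity loss: per protected cell,
interval-width/domain-range for numerics, (covered values − 1)/(domain
− 1) for categoricals, 1 for anything suppressed; averaged over the
protected cells (quasi-identifiers and sensitive targets; microaggregated
dates are excluded since mean-substitution has no natural width). The
lattice of level combinations is explored best-first, ordered by a
generalization-only lower bound that is monotone along the lattice, so
when the frontier empties the result is the global optimum — verified in
the tests against exhaustive enumeration on all instances with ≤ 8
records and ≤ 3 attributes. Large lattices (the context-independent
configuration has ~30 dimensions) hit a node cap, after which a steepest
descent from the fully suppressed node refines the best solution;
`search_complete` records which regime produced the answer, and the
result is the best of all nodes examined. Loss is monotone in k
(suppression sets only grow), and the context-independent configuration
suppresses at least as many records as the context-dependent one on the
same input — both asserted as properties.

## Synthetization

A desk-scale autoregressive chain stands in for a neural tabular
generator, reproducing the three safeguards such generators advertise:

1. **Broken 1:1 mapping** — sampling is ancestral from fitted
   conditional frequency tables; the model stores no rows.
2. **Overfit control** — attributes are discretized (quantile bins, 10
   by default) and each attribute's parent set (≤ 3) grows greedily,
   accepting a parent only if the total held-out log-likelihood improves
   by more than 2 nats (an AIC-scale margin that rejects selection
   noise; on mutually independent attributes ≥ 80% of parent sets stay
   empty, asserted in the tests). Laplace-style smoothing (0.5) is the
   regularizer; unseen parent configurations fall back to the marginal.
3. **Outlier protection** — numerics are clipped to the 1st/99th
   percentile before binning; categories with fewer than 5 training
   occurrences are pooled into a protected token that decodes to the
   attribute's modal value, so rare levels (the obesity flag) vanish
   from the release rather than leaking verbatim.

The chain order is the treatment column first — and the treatment column
is a *forced* parent of every later attribute (when non-constant) — then
schema order (demographics → comorbidities → study info → outcomes).
Forcing the arm variable is a deliberate deviation from a pure
greedy/causal ordering: arm-stratified distributions are the backbone of
every downstream analysis here, and greedy holdout selection can trade
the arm variable away for correlated comorbidities, silently biasing all
per-arm prevalences. Sampled numerics are uniform within their bin and
clipped to the stored bounds; equivalence with any vendor generator is
explicitly not claimed.

## Fidelity

* **Normalized prevalence**: within each arm, the protected flag
  prevalence as a percent of the original (baseline 100); suppressed
  attributes and zero-prevalence originals are flagged and excluded; the
  group-level summary is the mean of |normalized − 100|/100 (a
  fraction — the analogous published "average relative difference"
  values carry unstated units and are not asserted).
* **Correlation distance**: mean absolute difference of pairwise Pearson
  correlations over numeric attributes, binary flags included as 0/1
  (point-biserial equivalence); pairs undefined in either dataset (zero
  variance, e.g. a flag reduced to all-zero; or suppressed) are excluded
  and reported.
* **IPα / IRβ / authenticity**: columns are min-max normalized against
  the *original* data, missing values (including whole suppressed
  columns) imputed with the original column median — a documented caveat,
  since constant imputed columns distort distances. The α-support of a
  dataset is estimated by distance-from-centroid quantile balls: the
  α-ball is the sphere around the centroid containing the α-quantile of
  the dataset's own records. The precision curve c(α) = share of
  protected records inside the original's α-ball (recall swaps roles) is
  integrated against the ideal diagonal on a 20-point grid (trapezoid):
  `IP = clip(1 − 2·∫|c(α) − α| dα, 0, 1)`, so a same-distribution pair
  scores ≈ 1 and a disjoint-support pair 0. This ball estimator is a
  deliberate simplification of the one-class-embedding support estimator
  in the metric's original formulation; the metrics are used here as
  black-box diagnostics and the exact-copy / far-shift / same-generator
  behaviors are pinned by tests. Authenticity uses exact nearest
  neighbors: a protected record is authentic iff its nearest original
  neighbor is farther than that original's own nearest-neighbor distance
  within the original data (an exact copy is never authentic).

## Utility

Propensity scores come from an unpenalized logistic regression of the
exposed arm on age, gender and the comorbidity flags (constant columns
dropped — anonymization may zero a flag); a fitted |log-odds slope| > 15
is reported as separation with the culprit covariate named. Weights are
stabilized ATE weights (`P(T=1)/e` and `P(T=0)/(1−e)`), untruncated by
default with a configurable truncation quantile. Balance is the
standardized mean difference with the *unweighted* pooled SD in both the
before and after columns, so the two are on the same scale. Hazard
ratios come from a weighted Cox partial likelihood with treatment as the
sole covariate and a robust sandwich variance (required for valid CIs
under estimated weights); an arm with zero events yields `estimable =
False` and NA outputs rather than a number. The test suite verifies ≥
90% CI coverage of a planted hazard ratio of 1.25 over 100 replicates at
n = 5000.

## Privacy attacks

All record distances are Gower-style: range-normalized absolute
difference for numerics, 0/1 mismatch for categoricals, averaged over
attributes; distance ties resolve by record order. Each Anonymeter-style
attack runs a **main** attack on the training records behind the
release, a **naive baseline** (random predicates / random neighbor sets /
marginal-frequency guesses), and a **control** attack on an equally
sized independent holdout; the normalized risk is
`R = (r_main − r_control)/(1 − r_control)`. Risks are computed per
repetition and averaged (10 repetitions by default), with the SD and a
validity flag (main beats baseline) reported. Per-repetition risks are
clamped to [−1, 1]; a saturated control (r = 1) yields 0 when the main
attack is also saturated — without a guard the normalization is
ill-conditioned whenever the control attack is nearly perfect, which the
high published control rates (0.89–0.96) show is the realistic regime.
Equal-sized train and control splits are expected (the default pipeline
fractions are 0.35/0.35/0.30) because "matches exactly one record" is a
size-dependent event; a >10% size mismatch triggers a warning.

* **Singling-out**: univariate predicates are unique values and min/max
  thresholds observed in the release; multivariate predicates are
  conjunctions of 2–4 attribute equalities seeded from a random released
  record and kept only if they isolate exactly one released record
  (capped at 100 queries).
* **Linkage**: k-NN matching (k = 1 default) from each target to the
  release on two disjoint halves of the auxiliary attributes
  (alternating split); success = overlapping neighbor sets.
* **Attribute inference**: the nearest released neighbor on the
  auxiliary attributes predicts the secret; categorical secrets need an
  exact match, numeric ones a match within 5% of the release's range.

Scenario wiring: context-dependent attacks use the threat model's
indirect identifiers as auxiliary knowledge; context-independent attacks
use every attribute except direct identifiers (which no release retains).

**Membership inference** follows the shadow-model recipe: per run, draw
reference samples (500 records by default) from an attacker pool,
produce labeled protected datasets with the target included or excluded
(10 train and 10 test replicates per label), fit a random forest on
attribute-wise marginal features (binned counts / category frequencies,
bins fitted once on the pool), and aggregate TPR/FPR over 30 runs; risk
= TPR − FPR, negatives meaning no effective advantage. Replicate counts
are checked against the coverage criterion (each pool record sampled at
least once with ≥ 95% probability). Targets are selected by the mean
distance to the 5 nearest neighbors: the most isolated records are
outliers, the records nearest the median isolation are average targets
(10 + 10 by default). Shadow protections reuse the data holder's fixed
parametrization — hierarchies and configuration fitted once, never per
shadow sample — since refitted, data-dependent bin domains would leak the
target through the parametrization rather than the release.

Two findings from the reduced-scale checks worth knowing: (1) with
marginal-count features, even an identity release is only sharply
detectable when the target occupies histogram cells no pool record
shares, so the discrimination tests construct such a target — the
qualitative statement "no protection ⇒ membership observable" holds for
vulnerable records, not every record; (2) at reference-sample size 100
the context-dependent anonymizer shows a small but real mean membership
advantage (~0.1–0.2): the attributes classed insensitive pass through
unprotected, and one record in 100 shifts marginals five times more than
one in 500 — a concrete illustration of why the sample size of the
published protocol matters and why context-dependent protection rests on
the threat model being right.

## Pipeline and reporting

`run_all` simulates, splits (train/control/pool), classifies, protects
three ways, harmonizes (dates rebuilt from anchor + offsets for every
dataset), evaluates fidelity/utility on all four datasets, runs the
attack matrix under both scenarios, and optionally the membership
inference stage (off by default; it dominates the runtime). Reported
precision follows the conventions of the emulated study: risks to 2
decimals, percentages to 1, hazard ratios and CIs to 2; shares are
rounded to one decimal *before* differencing so proportional shifts
match what a reader computes from a printed table. Every stage is
seeded; rerunning with the same configuration reproduces the bundle.

Problem sizes in the test suite (cohorts of 120–900 records for the
anonymization soundness and attack-calibration checks, reference samples
of 100 with 5 runs and 5 targets for membership inference, n = 5000 ×
100 replicates for CI coverage) are the package's chosen desk-scale
conditions; the same code paths run unchanged at the full 1727-record
scale via `run_all` or the CLI.

## Known limitations

* The lattice search is optimal only when `search_complete` is true;
  beyond the node cap it is a documented heuristic.
* The α/β support-ball estimator assumes a roughly star-shaped support
  around the centroid; strongly multimodal data would need the original
  embedding-based estimator.
* The attack families implement one declared variant each (distance
  metric, baseline sampler, predicate widths); other choices in the
  cited frameworks may score differently, which is inherent to empirical
  privacy estimation.
* Synthetic-cohort realism is distributional, not clinical; absolute
  risk and utility numbers from this pipeline characterize the pipeline
  under the stated conditions, not any real dataset.
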