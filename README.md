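# privcohort

Compare **anonymization** and **synthetization** as protection methods for
small, high-dimensional health-claims cohorts, scoring each protected
dataset on three axes: **fidelity** (structural similarity to the source),
**utility** (reproducibility of a medication-safety survival analysis) and
**empirical privacy risk** (simulated re-identification attacks).

The package is aimed at biostatisticians and data custodians who must
decide *how* to share a sensitive cohort: it provides the full comparison
workflow as a tested library plus a thin CLI, exercised on a seeded
synthetic stand-in for a claims cohort of ~1700 patients with a first
venous thromboembolism (VTE) starting a direct oral anticoagulant (DOAC)
or a vitamin K antagonist (VKA).

## What it computes

**Protection.**
* *Anonymization*: k-anonymity (every equivalence class of
  quasi-identifier values holds ≥ k records) plus equal-distance
  t-closeness (per class, the total-variation distance between the
  sensitive-value distribution and the table's is ≤ t), enforced by
  generalization hierarchies (interval midpoints, category groups),
  attribute/record suppression and within-class mean microaggregation of
  dates. A bound-guided lattice search minimizes the granularity loss
  (mean fraction of each value's domain covered by its generalized
  representation; suppressed cells count 1) and is provably optimal on
  small lattices. Two configurations: *context-independent* (all
  attributes protected) and *context-dependent* (only the attributes a
  threat-modeling step classes as direct/indirect identifiers or
  sensitive), both with k=2, t=0.5.
* *Synthetization*: a seedable autoregressive chain of smoothed
  conditional frequency tables over discretized attributes, with rare
  categories pooled, numerics clipped to quantiles, and parent sets grown
  under held-out log-likelihood early stopping.

**Evaluation.**
* *Fidelity*: group-wise flag prevalences normalized to a baseline of
  100, mean absolute pairwise Pearson-correlation difference, and
  integrated α-precision / β-recall / authenticity in min-max-normalized
  space.
* *Utility*: stabilized inverse-probability-of-treatment weights from a
  logistic propensity model, standardized-mean-difference balance before
  and after weighting, and weighted Cox proportional-hazards ratios with
  robust 95% CIs for all-cause mortality and major bleeding (NA when an
  arm has zero events).
* *Privacy*: linkage, univariate/multivariate singling-out and
  attribute-inference attacks, each normalized as
  `R = (r_main − r_control) / (1 − r_control)` against a control attack
  on held-out records, plus shadow-model membership inference
  (`R = TPR − FPR`) against any protection procedure.

## Worked example

```bash
privcohort simulate --seed 3 --out cohort.csv
privcohort anonymize --in cohort.csv --context dependent \
    --out anon.csv --meta meta.json
privcohort utility --in anon.csv --out utility.json
privcohort synthesize fit --in cohort.csv --seed 2 --model m.json
privcohort synthesize sample --model m.json --n 1727 --seed 4 --out synth.csv
privcohort fidelity --original cohort.csv --protected synth.csv --out fidelity.json
```

prints (abbreviated):

```
wrote 1727 records to cohort.csv
{"suppressed_records": 163, "suppressed_attributes": ["patient_pseudonym"],
 "chosen_levels": {"age": 2, "index_offset_days": 2, ...}, "loss": 0.246, ...}
all_cause_mortality: HR 1.39 (0.67-2.86)
major_bleeding: HR 1.48 (0.74-2.95)
corr distance 0.030  IPa 0.972  IRb 0.954  auth 0.631
```

Reading this: the context-dependent anonymization of the 1727-record
cohort suppressed 163 records and the pseudonym column, generalized age
to 10-year midpoints and the day offsets to 90-day midpoints, at an
overall granularity loss of 0.246. The weighted Cox model on the
anonymized data still estimates hazard ratios near the cohort's planted
DOAC/VKA rate ratio of 1.25, with CIs spanning 1 (the emulated study's
events are rare). The synthetic release preserves pairwise correlations
to within 0.030 on average, sits almost entirely inside the original's
multivariate support (IPα 0.97), covers most of it (IRβ 0.95), and 63% of
synthetic records are not near-copies of any original record.

`privcohort run-all --seed 0 --out results/` executes the whole
three-way comparison (both anonymizations, synthetization, fidelity,
utility, and the attack suite under the context-dependent and
context-independent adversary scenarios) and writes `report.json` plus
the four dataset CSVs.

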