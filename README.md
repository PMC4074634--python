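# claimprev

Misclassification-adjusted prevalence estimation for a rare disease from
coded administrative insurance claims.

## The problem

National health-insurance billing databases record a diagnosis code per
claim, but for rare diseases such as systemic lupus erythematosus (SLE)
the code is often assigned tentatively: before definitive-diagnosis rules
were enforced, the ICD-10 code **M32** was attached to many patients who
were merely *suspected* of SLE.  The raw count of coded patients therefore
overstates prevalence, and the size of the overstatement — one minus the
code's **positive predictive value (PPV)** — must be measured by chart
review before the administrative count means anything.

`claimprev` implements the standard PPV-adjustment workflow for this
setting, aimed at epidemiologists working with claims extracts:

```
cases = N · p̂ ,     p̂ ± 1.96 · √( p̂(1−p̂) / n )      (Wald 95% CI)
```

where `N` is the number of distinct coded patients in the study window and
`p̂ = k/n` is the fraction of `n` chart-reviewed patients confirmed as true
cases (≥ 4 of the 11 ACR-1982 classification criteria).  Three
ascertainment routes are provided:

1. **Random sampling** — `p̂` from a verification sample drawn with
   stratified (region × hospital-type) proportional allocation, targets
   rounded by the largest-remainder rule;
2. **All registered patients** — `p̂` from a census of patients registered
   by specialist physicians;
3. **Subgroup analysis** — patients are grouped by their *visit pattern*,
   the subset of the three study years (lettered `a < b < c`) in which
   they had any coded billing; per-group PPVs from a reference institution
   are applied to the national group counts:
   `cases = Σ_g N_g · p̂_g` over the groups `abc, bc, ac, c`.

Because a national claims extract cannot be redistributed, the package
includes a first-class synthetic-claims generator with known ground truth
that emulates the statistical structure of such an extract (stratified
demographics, visit-pattern groups, per-stratum true-case probabilities,
duplicate billings, and chart-review criteria consistent with the latent
truth), so the whole pipeline is testable end to end.

## Worked example

The study conditions shipped as defaults: 13 652 coded patients over
2004–2006 whose visit-pattern groups number 7842 (`abc`), 1672 (`bc`),
260 (`ac`) and 3878 (`c`), a 2000-chart stratified verification sample
with 1343 confirmed, a 3504-patient census with PPV 0.6983, per-group
PPVs 0.90 / 0.76 / 0.36 / 0.57, and a national population of 48 890 000.

```python
from claimprev import (PPVEstimate, PatternTable, attach_population,
                       scale_estimate, subgroup_estimate)

ppv_a = PPVEstimate.from_counts(1343, 2000)      # p=0.6715, CI 0.6509-0.6921
est_a = attach_population(scale_estimate(13652, ppv_a), 48_890_000)
print(est_a.cases, est_a.cases_ci, round(est_a.per_100k, 1))
# 9167 (8886, 9448) 18.8

ppv_b = PPVEstimate.from_proportion(0.6983, 3504)
print(scale_estimate(13652, ppv_b, method="all_registered").cases)
# 9533

table = PatternTable(counts={"abc": 7842, "bc": 1672, "ac": 260, "c": 3878},
                     ppv={"abc": 0.90, "bc": 0.76, "ac": 0.36, "c": 0.57})
print(subgroup_estimate(table).cases)
# 10633
```

The three routes agree to within about 10%: 9167, 9533 and 10 633
estimated national cases, i.e. 18.8–21.7 per 100 000 people.  Interval
bounds are reported at 4 decimals; `ci_digits_mode="truncate"` truncates
them before scaling, which is how a published upper bound of 0.6920 yields
9447 rather than the default full-precision 9448.

The command line drives the same pipeline on files or simulations:

```sh
claimprev simulate --out-claims claims.csv --out-truth truth.csv \
                   --out-verify verify.csv --seed 42
claimprev estimate --claims claims.csv --verify verify.csv --population 48890000
claimprev repro --seed 0           # packaged study-conditions simulation
```

`claimprev repro` prints the three-method comparison table; with the
packaged defaults all three estimates land in the 9000–11 000 band.

## Input formats

* **Claims CSV** — one row per billing event with columns `patient_id,
  billing_year, region, hospital_type, department, service_type,
  age_years, sex`; categorical columns use closed vocabularies (see
  `claimprev.claims_core`), and unknown values are rejected.
* **Verification CSV** — `patient_id` plus the eleven ACR-1982 criterion
  columns (`malar_rash, …, fana_positive`) with 0/1 values; incomplete
  forms are rejected, never imputed.
* **Run config JSON** — study years, national population, sampling
  fraction, verification sizes, seeds (see `examples/demo_config.json`).

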