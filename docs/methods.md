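# Methods

## Model

The estimand is the number of true cases of a rare disease in a national
population, observed only through an administrative claims database in
which the diagnosis code is imperfect.  Let `N` be the number of distinct
coded patients over the study window and `p` the positive predictive
value of the code — the probability that a coded patient truly has the
disease, as judged by chart review against the ACR-1982 classification
rule (≥ 4 of 11 criteria).  The adjusted case count is `N·p`, with
uncertainty propagated from the PPV only:

```
p̂ = k/n,   CI95(p̂) = [ p̂ − 1.96·√(p̂(1−p̂)/n),  p̂ + 1.96·√(p̂(1−p̂)/n) ]
cases = round(N·p̂),   CI(cases) = round(N·CI95(p̂))
```

This is the plain Wald binomial interval with z fixed at 1.96 (not
recomputed from a normal quantile), clipped to [0, 1].  The model treats
`N` as a known constant: no uncertainty is attached to the claims count
itself, and sensitivity of the code (cases never coded at all) is not
modelled — the estimate is therefore a lower bound in the presence of
under-coding.  No capture–recapture or joint
sensitivity/specificity adjustment is attempted.

Three ascertainment routes estimate `p`:

* **random_sampling** — chart review of a stratified random sample of
  coded patients (strata: region × hospital type, proportional
  allocation, largest-remainder rounding, without-replacement uniform
  draws within strata);
* **all_registered** — chart review of a census of patients registered by
  specialist physicians, treated as a simple binomial sample of size `n`;
* **subgroup** — patients partitioned by *visit pattern*: the subset of
  the three study years (lettered `a < b < c`) with any coded billing,
  giving seven groups `a, b, c, ab, ac, bc, abc`.  Per-group PPVs
  measured at a reference institution are applied to the national group
  counts, `cases = Σ_g N_g·p̂_g` over `abc, bc, ac, c`.  No interval is
  produced for this route: the reference-institution group PPVs carry no
  reported variance, and inventing one would overstate what is known.
  The estimator's group set is overridable for sensitivity analyses; the
  default excludes `a`, `b` and `ab` (patients whose billing stopped
  before the final study year), whose predictive value is lowest.

A regional validation composes the same two steps — scale the local coded
count by a locally estimated PPV, divide by the local population — to
check the national estimate against an isolated region served by few
providers.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| study window | 2004–2006 | three consecutive calendar years; visit-pattern labels are specific to a 3-year window |
| z | 1.96 | normal critical value in the Wald interval |
| sampling fraction | 0.15 | share of coded patients targeted for review per stratum |
| review budget (method 1) | 2000 charts | overrides the fraction to a fixed total |
| census size (method 2) | 3504 charts | registered-patient review arm |
| national population | 48 890 000 | per-100 000 denominator (mid-2006); any output depending on it is flagged when absent |
| ci_digits_mode | `round` | see *Numerical conventions* |

The national population deserves a note: published per-100k figures are
only reproducible for denominators in a narrow back-solved interval
(≈48.887–48.891 million for the three case counts above); the default sits
inside it.  `population_range_for_rate` exposes the back-solving.

## Synthetic data generator

`claimprev.synthetic_claims` emulates a deduplicated national claims
extract.  Per patient it draws: a visit-pattern group; region, hospital
type, department, sex and age decade from categorical weights; a latent
`true_sle` flag, Bernoulli with the PPV its stratum implies; one claim row
per billed year plus occasional duplicate billings (rate 0.10, an
arbitrary but realistic level that exercises deduplication).  Chart review
is simulated by drawing the eleven criterion flags from per-status
marginal rates, rejection-resampled (budget 1000 tries) until
classification matches the latent truth exactly — the PPV arithmetic
assumes chart review is error-free, and the generator enforces that
assumption by construction.

Defaults encode the study conditions: 13 652 patients, female fraction
0.894, age peaked at 30–39, hospital mix 65.4% university / 17.9%
general / 15.8% private / 0.9% local, region weights led by Seoul 0.434,
group sizes `abc` 7842, `bc` 1672, `ac` 260, `c` 3878 (groups `a`, `b`,
`ab` get zero mass — their national sizes are not published — but can be
given mass for sensitivity runs), and group PPVs 0.90/0.76/0.36/0.57.
A second, mutually exclusive PPV map by hospital type
(0.65/0.70/0.76 private/general/university) reflects that the two maps
come from different sub-studies whose joint distribution is unknown; a
homogeneous mode serves calibration experiments.  The per-criterion
marginal rates are plausibility choices (near-universal ANA positivity
and frequent arthritis among true cases; sparse, ANA-dominated flags
among miscoded patients); only the ≥4/≤3 constraint, not the rates,
affects any estimator.

Two cohort-composition modes: `fixed` sets group counts exactly (needed
for digit-exact reproduction of worked examples and the default for the
repro pipeline) and `weights` draws them multinomially (used by the
coverage and recovery simulations, where fixed counts would understate
variance).  All randomness flows from one seed through
`numpy.random.SeedSequence` children, one per stage, so stages are
independently reproducible and simulated files are byte-identical across
runs.

What the simulator does *not* model — and hence what passing tests do not
establish about real extracts: under-coding (true cases never receiving
the code), chart-review error, correlation between demographics and
true-case status beyond the stratum PPV, longitudinal disease course,
mortality, incident-case growth across years, and real billing-number
semantics.  Tests demonstrate that the estimators are correct *given the
model*, not that the model captures any particular database.

## Numerical conventions

* PPVs and interval bounds are reported at 4 decimal places; case counts
  round half away from zero.
* `ci_digits_mode="round"` (default) scales case-count intervals from the
  full-precision Wald bounds; `"truncate"` truncates bounds to 4 decimals
  first.  Published tables computed from truncated bounds (an upper bound
  printed as 0.6920 where the full value is 0.692084, scaling to 9447
  rather than 9448) reproduce under `truncate`; reports carry the mode and
  digit count so the path is auditable.
* A Clopper–Pearson exact interval (`exact_ci`, via statsmodels) is
  available as an alternative to Wald but is not the reproduction path;
  no continuity correction is applied anywhere.
* Largest-remainder allocation breaks remainder ties toward the
  earlier stratum in sorted stratum order; allocations never exceed
  stratum sizes.
* Deduplication resolves conflicting demographics to the modal value,
  ties broken by first observation — deterministic given input order.
* Degenerate inputs: empty claims/verification inputs, zero-width
  intervals at p ∈ {0, 1}, and a zero local coded count (rate 0) are all
  defined behaviour; missing criterion values are rejected, not imputed,
  since silent imputation would bias the PPV toward the imputation rule.

## Design choices made where the design was open

* The national coded-patient total is interpreted as *unique patients*
  after deduplication, not billing lines: the visit-pattern group sizes
  sum exactly to it, and a partition by visit pattern is only meaningful
  for deduplicated patients.
* The extraction boundary is simplified to whole calendar years; group
  labels depend only on the year of the claim.
* The census arm is modelled as a simple random subset of the cohort of
  its published size; the number of participating hospitals is not
  modelled.
* In the end-to-end pipeline the subgroup route estimates its group PPVs
  from the census arm's verification records grouped by visit pattern (a
  reference-institution stand-in); the worked-example path instead takes
  the published group PPVs as inputs.
* Simulation problem sizes in the test suite are chosen to keep each
  stochastic check's Monte-Carlo error well inside its assertion band:
  500 replicates for recovery/coverage at full cohort scale, smaller
  cohorts (800–5000 patients) for structural properties.

## Known limitations

* Wald intervals undercover for extreme proportions and small n; at the
  verification sizes and PPVs used here (n ≈ 2000–3500, p ≈ 0.67–0.70)
  coverage is near-nominal, which the simulation suite checks directly.
* The three-year visit-pattern labelling does not generalise to windows
  of other lengths in this version.
* Group PPVs in the subgroup route inherit the reference institution's
  case mix; nothing corrects for transportability, and no variance is
  propagated for that route.
* `PPVEstimate.from_proportion` reconstructs the confirmed count by
  rounding `p·n`; it exists so published proportions can be used as
  inputs when the underlying count is unavailable, and inherits the
  rounding error of the published figure.
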