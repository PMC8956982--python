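# Methods

This note documents the statistical model, the data-processing
conventions, the synthetic-data generator, and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The concurrent risk-adjustment model

The analysis unit is the **enrollee-year**: one person's outcomes and
distinct diagnosis set within one calendar year. The model is
unconstrained weighted least squares,

    min_beta  sum_i w_i (y_i - x_i' beta)^2 ,

predicting a **concurrent** outcome (the same year as the diagnoses).
The design vector stacks:

* a **cell-means age–sex block**: sex crossed with age bands (defaults:
  0, 1–4, then 5-year bands through 60–64, i.e. 28 cells), every cell
  present and no intercept. Under this coding a diagnostically empty
  person is predicted by their demographic cell mean, and a negative
  prediction can only arise from the net effect of diagnostic
  coefficients — which is why the weighted share of negative predictions
  is a reported diagnostic. The exact cell layout is configurable via
  `age_band_edges` because reference implementations differ on the cell
  count (e.g. 29-cell layouts exist whose banding is not published).
* one **binary indicator per main-effect item** of each classification
  system in the model spec, set when any diagnosis in the year maps to
  the item. For hierarchical (`hcc_like`) systems, dominance rules are
  applied to the person-year's item set first. Modifier indicators and
  numeric scale columns (yearly maximum, plus an observed flag, absent
  encoded as 0) exist but are off by default: the headline comparison
  uses main effects only, so the value of the richer classification is
  attributable to the classification itself.

Indicator columns with zero prevalence in the development sample are
pruned at fit time and logged; validation matrices always use the
development column set. The default rich model is the flat comparator's
columns **plus** the multi-membership items, so the rich column set nests
the flat one and training R² is monotone by construction along that edge.

## Grouper semantics

* Codes are canonicalized to undotted uppercase. Syntax:
  `^[A-Z][0-9][0-9A-Z]{1,5}$` — the U block is accepted because
  emergency-use codes (COVID-19, vaping) live there. Chapters derive from
  the leading three characters via the WHO chapter ranges; ASCII ordering
  makes alphanumeric category heads (O9A) compare correctly.
* Lookup is exact-first; otherwise the **longest proper prefix of at
  least 3 characters** present in the table is used (source
  `root_stem`) — the 3-character minimum mirrors the ICD category root.
  Codes absent at every prefix return `unmapped` and are counted in run
  reports, never errors: user data may contain codes newer than any
  mapping. Root-stem fallback applies to the whole assignment (modifiers
  and scales included).
* A code may carry at most 4 main items; V–Z codes may legally carry
  modifiers only. Flat (`ccsr_like`) tables require exactly one main
  item per code. Hierarchy rules are data (a two-column TSV), validated
  to reference known items and to be acyclic; suppression is decided
  against the *original* person-year item set in one pass, which makes
  a severity chain a>b>c with all three present collapse to {a} and
  makes the operation idempotent and monotone.
* Scale values live in the mapping file (the code itself encodes the
  value, e.g. BMI bands in [18.5, 70]); conflicting observations within
  a year resolve to the maximum (severity-oriented), with
  "last observed" intentionally left out of scope of the default.

## Cohort construction

Per (person, calendar year), each outcome is processed in the fixed
order **sum → floor ($0) → global cap ($3M) → deflate → annualize →
analysis cap** ($250K for the primary spending outcome, $500K
out-of-pocket). Cleaning recodes precede analysis top-codes; the
analysis cap acts on the annualized value. Annualization divides by the
enrolled fraction of the year (whole months / 12; "at least one month"
is the eligibility floor) and the regression weight equals that
fraction — except **newborns**, whose birth-episode spending is not a
rate: their outcomes are kept raw and their weight is 1. Deflators are
required inputs per year (no CPI series is bundled). With floors, caps
and deflation disabled, the weighted mean of annualized outcomes equals
total spend divided by total enrolled years over non-newborns — the
money-conservation identity the acceptance battery checks.

Diagnosis filtering restricts which diagnoses count (an
acceptable-source rule table over (setting, professional-type) pairs,
`*` wildcards allowed; unknown settings route to `other`); it never
removes payments. Removals are tallied by source in the run report, and
kept + removed always equals input.

The development/validation split is **by person** (all of a person's
years on one side), each person drawn independently with the validation
probability, deterministic under the seed. Whether the original split
of this design was by person or person-year is not documented anywhere
we could verify; by-person is the conservative choice against leakage.

## Estimation

The solver forms the weighted Gram matrix X'WX once (sparse X, dense
Gram) and uses a greedy rank-revealing Cholesky sweep: columns are kept
in order while their pivot exceeds `1e-10` relative to their diagonal,
so collinear columns drop deterministically (first kept wins) and are
logged. Standard errors and p-values are classical WLS (sigma² from the
weighted RSS with n − k degrees of freedom); cluster-robust machinery is
deliberately confined to the evaluation module's residual intervals.

Stepwise selection is SAS-flavored forward-with-removal with the same
entry and stay thresholds (default P < 1e-4). Entry p-values for all
candidates are computed per step from Schur complements on the Gram
matrix — an O(k²) update per candidate instead of a refit — with ties
broken by column name. After each entry, entered non-forced columns
whose p-value has risen to or above the stay threshold are removed,
worst first (the removal step is switchable off). The age–sex block is
forced: always in, never removable. Note the degenerate limit
`entry_p → 0` retains only the forced block *on null candidates*; a
strong true signal may reach a p-value that underflows to exactly 0.0
in double precision, and a zero p-value is below any representable
threshold.

Bonferroni significance flags use threshold `min(alpha/m, 1e-4)` with a
strict comparison; the family size m defaults to the number of candidate
columns considered (not just those retained), the conservative reading.

## Evaluation

All metrics are weighted: R², MAE, and the Cumming prediction measure
modified to carry the sample weights, CPM = 1 − Σw|y−ŷ| / Σw|y−ȳ_w|,
with the null predictor ȳ_w being the weighted mean of the evaluation
sample itself. CPM and R² may legitimately be negative out of sample.

Predictive ratios bin rows by **type-1 (interpolation-free) weighted
quantiles** of the actual outcome, lower-edge inclusive — stated here
for bit-reproducibility — and report weighted mean actual, mean
predicted, and their ratio per bin; a zero-mean bin reports a missing
ratio.

The rare-diagnosis analysis assigns each enrollee-year's residual, with
its regression weight, to every distinct diagnosis the enrollee had that
year; diagnoses are binned by frequency per million enrollee-years at
powers of 10. Frequencies may come from the empirical full (pre-split)
sample (`compute_code_frequencies`) or from known population frequencies
when available (the synthetic generator's ground truth) — at 10^5
enrollee-years the empirical floor is 10 per million, so the
≤10-per-million bin is only measurable against known frequencies. The
95% intervals are corrected for clustering at the patient level by
aggregating each person's weighted contributions per bin and using the
between-person variance of the weighted mean (normal approximation).
Codes missing from the frequency table route to the rarest bin and are
logged. The regression weights serve as the "enrollee weights"; unit
weights are a caller choice.

## The synthetic generator

The generator emulates the *statistical structure* the framework
assumes, not any real population:

* **Frequency spectrum**: per-code frequencies log-uniform between 1 and
  100,000 per million enrollee-years (~1 in a million to ~1 in 10), so
  every power-of-10 bin is populated. Defaults: 2,000 disease codes plus
  modifier-only Z codes and a BMI scale block; 100,000 persons; one
  calendar year (multi-year runs age persons forward).
* **Mapping structure**: common codes get narrow items in
  frequency-contiguous blocks, a configurable share also carry an
  overlapping broad item; rare codes are pooled into rare-disease items
  wide enough to estimate — the design feature multi-membership
  classification exists for. The flat comparator stripes its categories
  across the frequency spectrum so each category mixes common-cheap with
  rare-expensive codes (diluting rare effects), and the hierarchical
  comparator covers only the common top of the spectrum with a 3-level
  severity chain.
* **Spending**: annualized rate = age–sex base + Σ item effects over the
  person-year's items, with item effects lognormal (medians $800 narrow,
  $8,000 rare-pool, $300 broad — heavy-tailed so rare conditions are
  expensive). Noise is additive, mean-zero, lognormal-shaped with a hard
  left bound at −$1,000 (below every base rate, so organic totals are
  nonnegative) and is homoscedastic in annualized terms; observed raw
  spend is the rate times the enrolled fraction, making annualization
  exact. Newborn spending is a birth episode, not exposure-scaled.
  A 0.2% share of person-years is overwritten with small negative
  totals (exercising the $0 floor) and 1% receive a catastrophic
  episode above $250K (exercising the analysis top-code); both are
  independent of the diagnostic profile, so they shift demographic cell
  means without biasing item coefficients.
* **Claims plumbing**: 5% of diagnosis lines are routed to disallowed
  sources and 10% are duplicated, exercising the filter and the
  set-semantics of the diagnosis set. Spending truth is driven by the
  diagnoses that survive the default acceptable-source rules, so a
  default pipeline run can recover the generating coefficients exactly.

What the generator does **not** emulate: real ICD clinical semantics,
diagnosis-conditional catastrophic spending (extremes are independent of
items, which keeps coefficient recovery unbiased but makes overall R²
levels lower than real-world concurrent models), coding intensity
differences across settings, capitated plans, or calibration to any real
claims moments. Passing tests therefore demonstrate correctness of the
machinery and the qualitative coarse-vs-rich phenomena, not real-data
performance levels.

## Reference experiment sizes

The acceptance battery runs at the generator's reference conditions:
100,000 person-years for the model ladder, coefficient recovery
(coverage of ±3 classical SEs; the noise design above is what makes
classical SEs approximately valid, the remaining slack coming from the
weight/variance mismatch of partial-year rows), and the rare-diagnosis
experiment. The rare-diagnosis experiment switches catastrophic episodes
and negative adjustments off so the ≤10-per-million bin — a handful of
validation pairs at this scale — isolates the rare-code signal; with
them on, a single catastrophic draw landing in a 13-pair bin would
dominate its mean. Oracle equivalence uses 100 random instances up to
1,000 rows × 50 columns against the explicit normal-equations solution.

## Known limitations

* The Gram-based solver is dense in the column dimension: comfortable to
  a few thousand columns, not engineered for 10^5-column designs.
* Classical (non-robust) SEs are reported by design for selection and
  flags; heteroscedasticity-robust SEs for the regression itself are out
  of scope.
* Prospective (next-year) models, prescription-drug adjusters,
  constrained/reinsurance payment variants, and ML fitters are
  deliberately out of scope.
* `FittedModel.from_json` / run manifests capture coefficients and
  traces, not the full design-matrix provenance; reproducibility is by
  config + seed.
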