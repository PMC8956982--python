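# dxikit

Concurrent risk-adjustment modeling over rich diagnostic classifications
for claims data.

Health plans are paid, and clinicians are benchmarked, through models that
predict spending from enrollee diagnoses. The coarser the diagnosis
grouper behind such a model, the more it mis-prices people with rare or
finely differentiated conditions — a selection problem, since those people
become predictably unprofitable. `dxikit` is a toolkit for building and
evaluating *concurrent* (same-year) risk-adjustment models over
multi-membership diagnosis classifications — systems in which one
ICD-10-CM code may map to several overlapping broad and narrow items —
and for quantifying exactly where coarse groupers fail: in the tail of
the diagnostic-frequency spectrum.

It is aimed at health-economics and health-services researchers who work
with enrollee-level claims: it ships no clinical mapping content of its
own, but loads any mapping in a documented TSV format and includes a
seeded synthetic-claims generator with known ground truth for method
validation.

## What is in the box

* **`dxikit.mapping`** — a diagnosis grouper: items of three kinds
  (binary main effects, up to 4 per code; cross-cutting modifiers;
  numeric scales such as BMI bands), exact lookup with longest-prefix
  root-stem fallback, comparator systems in the same machinery (flat
  single-membership "CCSR-like"; hierarchical "HCC-like" with dominance
  rules), and per-chapter summaries.
* **`dxikit.cohort`** — enrollee-year construction: diagnosis filtering
  by acceptable (setting, professional-type) pairs, outcome cleaning
  ($0 floor, $3M recode), CPI deflation, annualization to a 12-month rate
  with regression weight equal to the enrolled fraction of the year
  (newborns exempt, weight 1), analysis top-codes ($250K/$500K), and a
  by-person development/validation split.
* **`dxikit.features` / `dxikit.estimation`** — scikit-learn-style
  estimators: `DesignMatrixBuilder` (fit/transform) produces named sparse
  matrices of age–sex cells plus item indicators; `WeightedLeastSquares`
  and `StepwiseWLS` (fit/predict, `get_params`, fitted `*_` attributes)
  implement weighted least squares and forward selection with a p-value
  entry criterion (default P < 1e-4) computed by Gram-matrix Schur
  updates, with Bonferroni-corrected significance flags.
* **`dxikit.evaluation`** — validation-sample metrics: weighted R² and
  MAE, the weighted Cumming prediction measure
  CPM = 1 − Σw|y−ŷ| / Σw|y−ȳ_w| (an L1 analogue of R²), predictive
  ratios by weighted percentile of actual spending, and mean residuals
  binned by diagnostic frequency (powers of 10 per million
  enrollee-years) with patient-clustered 95% intervals.
* **`dxikit.synth`** — the synthetic generator: log-uniform diagnosis
  frequencies spanning ~1 per million to ~1 in 10 enrollee-years,
  multi-membership mappings with broad/narrow overlap and rare-disease
  pools, spending from a known linear model with heavy-tailed noise,
  injected negative totals and catastrophic episodes.
* **`dxikit` CLI** — `simulate`, `build-cohort`, `group`, `fit`,
  `evaluate`, `compare`, and a config-driven `run`.

## The model

For enrollee-year $i$ with annualized outcome $y_i$ and weight $w_i$
(fraction of the year enrolled), the concurrent model is unconstrained
weighted least squares

$$\min_\beta \sum_i w_i\,(y_i - x_i'\beta)^2,$$

where $x_i$ stacks a cell-means age–sex block (every cell, no intercept)
and one indicator per diagnostic item that any of the year's diagnoses
maps to. Stepwise fits start from the forced age–sex block and enter the
candidate with the smallest entry p-value while it is below the
threshold, re-checking entered columns for removal. Model quality is
always reported on a held-out validation sample.

## Worked example

```python
from dxikit import (SimConfig, simulate, build_enrollee_years,
                    default_outcome_specs, split_sample)
from dxikit.features import DesignMatrixBuilder, ModelSpec
from dxikit.estimation import WeightedLeastSquares
from dxikit.evaluation import evaluate_model, compare_models

data = simulate(SimConfig(n_persons=20_000, seed=42))
table, report = build_enrollee_years(
    data.enrollment, data.claims, default_outcome_specs(), {2018: 1.0},
    filter_rules=data.maps.default_filter_rules)
dev, val = split_sample(table, 0.10, seed=42)

reports = []
for name, systems in [("age_sex", ()), ("hcc", ("hcc_like",)),
                      ("ccsr", ("ccsr_like",)), ("dxi", ("ccsr_like", "dxi"))]:
    spec = ModelSpec(outcome="total_topcoded", systems=systems)
    builder = DesignMatrixBuilder(mappings=data.maps.tables, spec=spec)
    X_dev, X_val = builder.fit_transform(dev), builder.transform(val)
    model = WeightedLeastSquares().fit(X_dev).result()
    reports.append(evaluate_model(model, X_val, model_id=name))
print(compare_models(reports)[["n_variables", "weighted_r2",
                               "weighted_mae", "weighted_cpm"]].round(4))
```

Output:

```text
         n_variables  weighted_r2  weighted_mae  weighted_cpm
model
age_sex           28       0.0008     8154.1766       -0.0167
hcc               43       0.0333     7343.1017        0.0844
ccsr              68       0.0427     6796.3271        0.1526
dxi              325       0.0722     5165.8569        0.3559
```

Each row is one model evaluated on the same 10% validation sample of
20,000 synthetic enrollee-years, predicting total spending top-coded at
$250,000. Demographics alone explain almost nothing; the hierarchical
comparator (which covers only common codes) improves on it; the flat
single-membership comparator improves further; and the multi-membership
item model — which nests the flat comparator's columns and adds items
fine enough to carry rare-disease effects — gives the best validated R²,
the lowest weighted mean absolute error, and the highest weighted Cumming
prediction measure. On this generator the richer classification roughly
halves the rare-diagnosis mean residual bins relative to the flat model
(see `dxikit.evaluation.residuals_by_frequency`).

The same ladder runs from the shell:

```bash
dxikit run --config examples/config.yaml --out-dir run/
```

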