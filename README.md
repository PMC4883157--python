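# cmbayes

Evidence-based evaluation of binary classification results.

A 2×2 confusion matrix (rows = true classes, columns = predicted
classes) is scored as a **Bayesian test of statistical independence**
between predicted and true labels: with the row margins fixed, each row
is a binomial draw, H0 says the two success probabilities coincide
(classifier carries no information), H1 says they differ. The Bayes
factor of H1 against H0 uses an intrinsic prior that concentrates mass
near the null, controlled by non-negative integer concentration
parameters `(t1, t2)`; the reported statistic is the **conservative
minimum of log B10 over the concentration grid** (`t_i ∈ {0..min(t_max,
n_i)}`, `t_max` defaulting to the test-set size `m`). All logarithms are
natural; log B10 is mapped onto the qualitative scale *negative / bare
mention / positive / strong / decisive* (bands `(-inf,0)`, `[0,1)`,
`[1,3)`, `[3,5)`, `[5,inf)`).

Alongside the Bayes factor, the standard metrics it is compared against
are computed: prediction accuracy, TPR/FPR/specificity, MCC, F1,
Cohen's κ and Youden's J. Metrics with a zero denominator are reported
as *undefined* (`null` in JSON), never silently coerced to 0. Unlike
those metrics, the evidence statistic is sensitive to the test-set
size: scaling all counts down leaves every standard metric unchanged
but shrinks the evidence.

The package also ships:

- `cmbayes.validation` — independent oracles (beta-binomial closed
  forms and direct numerical quadrature) that re-derive both marginal
  likelihoods so any reported Bayes factor can be audited at small scale;
- `cmbayes.simulate` — a reproducible row-binomial confusion-matrix
  generator and a comparison runner (metrics vs. evidence per replicate).

## CLI

```sh
# evaluate one matrix (inline counts, row-major) — JSON on stdout
cmbayes evaluate --counts 80 10 0 10 --pretty

# or from a headerless 2x2 CSV/TSV, or JSON {"matrix": [[..],[..]], ...}
cmbayes evaluate --matrix confusion.csv

# options: --t-max (grid cap, default m), --prior-odds (default 1.0),
#          --positive-row {1,2} (default 2), --ref-column {1,2}, --log-level
```

Example output fields: `metrics` (undefined → `null`), and `bayes` with
`log_b10_min`, `argmin`, `evidence`, `posterior_odds`, `grid_spread`
and `truncated_grid`. Warnings (grid truncation, instability of log B10
across the grid, undefined metrics) go to stderr only.

```sh
# run simulated scenarios: tidy CSV of replicates + JSON summary
cmbayes simulate --scenarios scenarios.json --out-prefix out/run
```

A scenario is `{"n1":.., "n2":.., "p1":.., "p2":.., "n_reps":..,
"seed":..}` or a fixed matrix `{"matrix": [[..],[..]], "name": ".."}`;
a bundled file with the four canonical 100-example test cases is at
`cmbayes.simulate.reference_cases_path()`.

## Library

```python
from cmbayes import ConfusionMatrix2, full_report, min_log_bayes_factor

cm = ConfusionMatrix2.from_rows([[80, 10], [0, 10]])
full_report(cm).to_dict()            # pa=0.9, mcc=0.6667, kappa=0.6154, ...
res = min_log_bayes_factor(cm)       # log_b10_min=10.67 -> "decisive"
```

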