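# cytoms

Serum-cytokine classification pipeline for multiple sclerosis (MS).

Elevated serum cytokines (IL-1β, IL-2, IL-4, IL-10, IL-13, IFN-γ, TNF-α,
with IL-8 shifting in a population-dependent direction) distinguish MS
patients from controls, and — together with age, gender, EDSS, MSSS and
disease duration — carry signal about the disease course. `cytoms` is a
Python library for building and evaluating classifiers on such panels when
the available data is a mix of individual-level measurements and published
summary statistics:

- **Summary-statistic reconstruction.** Individual values are recovered
  from `mean ± SD/SEM` under a normal assumption by the inverse-normal
  percentile method: n midpoint percentiles inside the central 99.7% of
  mass, `xᵢ = μ + σ·Φ⁻¹(pᵢ)`, with SEM converted to SD via `SEM·√n`. The
  published mean is reproduced exactly; the SD shrinks by a known,
  documented constant.
- **Synthetic cohorts.** A generator produces MS/control cohorts with exact
  demographic quotas (e.g. 46/31/20 across the three MS courses in a 97-
  patient cohort) and lognormal cytokine marginals shifted by a standardized
  effect size d per analyte, so every downstream stage is testable without
  access to patient data.
- **Balanced voting ensembles.** An unbalanced training set (say 750 MS vs
  150 controls) is handled by partitioning the majority class into
  ⌈750/150⌉ = 5 parts, pairing each with all 150 controls, training one
  classifier per balanced subset (SVM-RBF, decision tree, 500-tree random
  forest with mtry = 2, or a 5-unit neural net), and combining test
  predictions by majority vote; the vote fraction is the ensemble's ROC
  score.
- **Evaluation.** Accuracy (0–100), sensitivity TP/(TP+FN), specificity
  TN/(TN+FP), trapezoidal AUC, Gini = 2·AUC − 1, and repeated stratified
  k-fold cross-validation (default 6 × 3) of the full pipeline, with the
  across-fold accuracy SD as the robustness criterion.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

`examples/diagnose_ms.py` pools three synthetic cohorts (833 + 26 USA-like,
51 + 71 Russian-like records) into 910 MS + 199 controls, draws 750/150
into training, balances, trains all four ensembles and evaluates them on
the 209 held-out records:

```
train 900 / test 209; 5 balanced subsets of sizes [300, 300, 300, 300, 300]

model            gini    acc%    auc   sens   spec
svm_rbf         0.846   89.00  0.923  0.894  0.878
decision_tree   0.788   83.25  0.894  0.800  0.939
random_forest   0.837   88.52  0.918  0.881  0.898
neural_net      0.866   89.95  0.933  0.912  0.857
```

Each row is one majority-voting ensemble: `acc%` is the percentage of the
209 test records labelled correctly, `sens`/`spec` the true-positive and
true-negative rates with MS as the positive class, `auc` the area under the
vote-fraction ROC curve and `gini` its rescaling 2·AUC − 1. The synthetic
effect size here is d = 0.8 per analyte, so all four families sit well
above chance.

The other examples cover cohort generation (`generate_cohort.py`),
reconstruction from summaries (`reconstruct_from_summaries.py`), the
remitting vs non-remitting course task (`classify_course.py`), and repeated
cross-validation (`cross_validate.py`). Each prints its numbers with a line
on what they mean.

A thin CLI wraps the same stages:

```sh
cytoms generate --label demo --n-ms 97 --n-control 71 --seed 7 --out demo.csv
cytoms assemble --cohort demo.csv --train-ms 70 --train-control 50 --outdir asm/
cytoms run-all --config run.yaml --outdir results/
cytoms cv --config run.yaml --family random_forest
```

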