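# Methods

`cytoms` implements a serum-cytokine classification pipeline for multiple
sclerosis (MS): reconstruction of individual-level records from published
summary statistics, cohort synthesis, class balancing by majority-class
partition, majority-voting classifier ensembles, and a confusion-matrix /
ROC / cross-validation evaluation suite. This note records the model
assumptions, parameter defaults, and the design choices made where the
procedure was genuinely open.

## Summary-statistic reconstruction (inverse-normal percentile method)

Published cytokine panels frequently report only `mean ± SD` or
`mean ± SEM` per group. Assuming a normal population, n individual values
are reconstructed by placing n midpoint percentiles inside a central
probability mass m (default 0.997, the remaining 0.3% treated as outliers)
and mapping them through the inverse normal CDF:

    p_i = (1 − m)/2 + (i − ½)/n · m,   value_i = μ + σ·Φ⁻¹(p_i),  i = 1…n.

SEM entries are first converted to SD by multiplying by √n.

Numerical properties, all tested:

- **Mean preservation.** The grid is symmetric about p = 0.5, so the sample
  mean equals μ to machine precision for every n — including n = 1, where
  the single value is the median μ.
- **SD shrinkage.** The sample SD is a deterministic constant below σ
  (≈ 0.985·σ at n ≈ 1000 for m = 0.997, converging to the truncated-normal
  SD over the central mass). No rescaling is applied to undo it: the
  procedure as specified performs none, and the constant is exposed as
  `grid_sd_shrinkage(n, mass)` rather than hidden.
- **Bounded support.** All values lie strictly inside
  μ ± σ·Φ⁻¹((1 + m)/2); the mass between the bounds is m to 1e−12.

The midpoint placement (i − ½)/n was chosen over alternatives such as
i/(n+1) because it is the unique symmetric, deterministic rule that
preserves the mean exactly at every n. The 0.3% exclusion is read as
bounding the percentiles, not discarding subjects: n values are always
produced.

**Coupling.** Per-cytokine value vectors must be assigned to subjects. The
default (`independent`) applies an independent seeded permutation per
cytokine, fabricating no inter-analyte correlation; `comonotone` gives
subject i the i-th order statistic of every analyte (perfect rank
correlation). Neither is "right" — the published summaries contain no
correlation information — but independence is the conservative default for
downstream classifiers.

**Negative values.** When σ ≳ μ/3 the lower grid tail goes below zero.
Values are kept by default (preserving the stated moments) with a logged
warning; `clamp_negative=True` clips at 0 pg/mL at the cost of a small
upward mean bias.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline was designed for:
two groups (MS, control) with per-analyte location shifts, and the
demographic/clinical structure of a directly measured cohort of 97 MS / 71
controls (age 39.1 ± 13.4 vs 28.6 ± 8.8 years; 67/97 vs 53/71 female;
courses 46 relapsing-remitting, 31 secondary progressive, 20 primary
progressive; disease duration 3.9 ± 2.2 y; EDSS 2.6 ± 1.5; MSSS 4.9 ± 2.3;
22/97 on treatment). Course, gender and treatment counts are assigned by
exact largest-remainder quota, not i.i.d. sampling, so the published counts
are reproducible exactly at the published n.

- **Cytokine marginals** default to lognormal, parameterized by the target
  mean and SD on the concentration scale (serum concentrations are positive
  and right-skewed); a normal family clipped at 0 pg/mL (clipping logged) is
  available for parity with the reconstruction module's normality
  assumption. The MS mean is `control_mean + d·control_sd` with d the
  standardized shift.
- **Default effect sizes are free parameters.** No per-analyte means or SDs
  were published for the directly measured cohort, so the defaults (control
  levels of order 1–15 pg/mL, d = 0.8 on the seven analytes consistently
  elevated in MS — IL-1β, IL-2, IL-4, IL-10, IL-13, IFN-γ, TNF-α — and IL-8
  at ∓0.5, lower in the USA-like and higher in the Russian-like population)
  encode direction and a plausibly large biomarker effect, nothing more.
  Passing tests on these cohorts demonstrates that the pipeline recovers
  signal that is present, not that real cohorts carry this much signal.
- **Independence across analytes** by default (an optional latent-factor
  equicorrelation is provided); real cytokine panels are correlated, which
  the defaults deliberately do not claim to model.
- EDSS/MSSS/duration are drawn normal and clipped to valid ranges
  ([0, 10] for the scores, ≥ 0 for duration), clipping logged. Clinical
  covariates are independent of the cytokines and of the course label, so
  synthetic course classification hovers at the majority rate by design.

## Splitting and balancing

`shuffle_and_split` draws training membership uniformly at random per class,
either by exact per-class counts (`by_count`, the default — e.g. 750 MS +
150 controls out of 910/199 leaves a 209-record test set, reproducing the
published arithmetic, which a literal 70/30 of 1109 would not) or by a
class-stratified fraction (`by_fraction`). The test set is the unbalanced
remainder.

`balance_by_subsets` partitions the majority class into
⌈n_maj/n_min⌉ near-equal parts (largest-remainder sizing, seeded
assignment, sizes differing by at most 1) and pairs each part with the full
minority class. Every majority record is used exactly once across subsets;
with n_maj = k·n_min each subset has exactly 2·n_min rows. An override
forces a fixed subset count when strict replication of a five-subset layout
is wanted.

## Classifier bank and voting ensemble

Four families behind one contract (deterministic given seed, scores in
[0, 1], preprocessing fitted on training data only):

| family        | back-end                 | tuning                              |
|---------------|--------------------------|-------------------------------------|
| svm_rbf       | SVC, Platt probabilities | RBF kernel; C = 1, γ = 'scale' (logged defaults) |
| decision_tree | DecisionTreeClassifier   | min_samples_split = 20, max_depth = 30 |
| random_forest | RandomForestClassifier   | max_features (mtry) = 2, 500 trees  |
| neural_net    | MLPClassifier            | one hidden layer of 5 logistic units; lbfgs, max_iter = 1000 (logged defaults) |

Min–max scaling to [0, 1] is applied for the scale-sensitive families
(svm_rbf, neural_net) only; trees consume raw features. Gender is a single
0/1 indicator (F = 1); unseen levels at prediction time are an error, not a
silent zero. The random-forest score is the fraction of trees voting
positive — a grid on {0, 1/500, …, 1} — rather than the back-end's averaged
leaf probabilities, so the ensemble vote semantics are exact.

`fit_ensemble` trains one member per balanced subset with member seeds
derived deterministically from the master seed. At prediction time each
member casts its 0.5-thresholded vote; the ensemble label is the strict
majority, and the vote fraction is the ensemble's ROC score (mean of member
probabilities available as an alternative — with a single subset the vote
fraction is binary and its ROC is coarse). **Tie rule** (even member counts
only): ties go to the positive (disease) class, favouring sensitivity in a
screening context; configurable.

## Evaluation

Accuracy = (TP+TN)/(TP+TN+FP+FN)·100 (reported on 0–100); sensitivity =
TP/(TP+FN); specificity = TN/(TN+FP); AUC by trapezoidal threshold sweep
(equal by construction to the pair-counting statistic with midpoint tie
handling); Gini = 2·AUC − 1, enforced as an identity. Sensitivity and
specificity with an empty denominator are reported as missing, never as 0.

Repeated k-fold CV (default 6 folds × 3 repeats = 18 cells) re-runs the
*entire* pipeline — balancing and ensemble training — inside every fold on
a fresh seeded stratified partition; the SD across cells is the robustness
criterion (default threshold 5 percentage points, configurable).
Stratification is a deliberate strengthening over plain equal portions so
every fold retains both classes at small n.

## Problem sizes and determinism

The test and acceptance runs use synthetic cohorts of 600–1200 records and
ensembles of up to 5 × 500-tree forests — sizes at which every stage's
bookkeeping (900/209 split, 5 × 300 subsets, 18 CV cells) matches the
published layout exactly while a full run completes in well under a minute
per workflow. All randomness flows from explicit integer seeds: cohort
generation, splits, balancing, member training and fold construction are
each seeded deterministically from a master seed, and identical
configurations produce byte-identical outputs (verified via manifest file
hashes).

## Known limitations

- Synthetic cohorts carry no inter-cytokine correlation, no
  covariate–cytokine dependence, and no course-dependent signal by default;
  results on them bound what the pipeline can do, not what real serum
  panels support.
- The reconstruction's SD shrinkage (≈ 1.5% at m = 0.997) is inherent to
  the truncated grid; analyses sensitive to exact second moments should
  account for it.
- SVM probabilities come from Platt scaling with its internal CV; they are
  deterministic given the seed but not calibrated beyond what Platt scaling
  provides.
- The remitting/non-remitting task collapses three courses into two; no
  ordinal or multi-class treatment is attempted.
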