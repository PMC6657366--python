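"""Full diagnosis workflow: MS vs control from the 8-cytokine serum panel.

Reproduces the published bookkeeping on synthetic analogs: pooled 910 MS +
199 controls, 750/150 drawn into training (900 train / 209 test), the 750
training patients partitioned into 5 balanced subsets, one classifier per
subset, majority-voting ensemble evaluated with accuracy, sensitivity,
specificity, AUC and Gini.
"""

from cytoms import RunConfig, SplitSpec, run_prediction_workflow

config = RunConfig(
    cohorts=[
        {"generate": {"cohort_label": "usa_large", "n_ms": 833,
                      "n_control": 117, "panel_direction": "usa"}},
        {"generate": {"cohort_label": "usa_small", "n_ms": 26,
                      "n_control": 11, "panel_direction": "usa"}},
        {"generate": {"cohort_label": "russian", "n_ms": 51,
                      "n_control": 71, "panel_direction": "russian"}},
    ],
    feature_set="target_1_1",
    families=["svm_rbf", "decision_tree", "random_forest", "neural_net"],
    split=SplitSpec(mode="by_count", train_ms_count=750,
                    train_control_count=150, seed=0),
    seed=0,
)

manifest, reports = run_prediction_workflow(config)
print(f"train {manifest['n_train']} / test {manifest['n_test']}; "
      f"{manifest['subset_count']} balanced subsets of sizes "
      f"{manifest['subset_sizes']}")
print(f"\n{'model':14s} {'gini':>6s} {'acc%':>7s} {'auc':>6s} "
      f"{'sens':>6s} {'spec':>6s}")
for family, rep in reports.items():
    print(f"{family:14s} {rep.gini:6.3f} {rep.accuracy:7.2f} {rep.auc:6.3f} "
          f"{rep.sensitivity:6.3f} {rep.specificity:6.3f}")
print("\nEach row is one voting ensemble on the held-out 209 records; "
      "Gini = 2*AUC - 1. On these synthetic cohorts (effect size d = 0.8 "
      "per analyte) every family separates the groups well above chance.")
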