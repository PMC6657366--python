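"""Confusion metrics, ROC/AUC/Gini, repeated k-fold CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoms.evaluation import (
    ConfusionCounts,
    confusion,
    metrics,
    repeated_kfold,
    roc_auc,
)


def pair_counting_auc(scores, truth):
    """Exhaustive oracle: P(score_pos > score_neg) + 0.5 P(equal) over all
    positive x negative pairs."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_constant_positive_predictor(self):
        c = confusion([1] * 10, [1] * 3 + [0] * 7)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 7, 0, 0)

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 50)
        true = rng.integers(0, 2, 50)
        c = confusion(pred, true)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for p, t in zip(pred, true):
            key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"])
        assert c.total == 50

    def test_length_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_published_gini_auc_pairs(self):
        """Gini = 2*AUC - 1 reproduces the reported pairs (e.g. AUC 0.931
        with Gini 0.862)."""
        c = ConfusionCounts(tp=1, tn=1, fp=0, fn=0)
        assert metrics(c, auc=0.931).gini == pytest.approx(0.862, abs=5e-4)
        assert metrics(c, auc=0.957).gini == pytest.approx(0.914, abs=5e-4)
        assert metrics(c, auc=0.783).gini == pytest.approx(0.566, abs=5e-4)

    def test_chance_level_gini_is_zero(self):
        c = ConfusionCounts(tp=1, tn=1, fp=1, fn=1)
        assert metrics(c, auc=0.5).gini == pytest.approx(0.0)

    def test_constructed_confusion_table(self):
        """TP=75 TN=115 FP=19 FN=0 on 209 records: accuracy 190/209*100,
        sensitivity 1, specificity 115/134."""
        rep = metrics(ConfusionCounts(tp=75, tn=115, fp=19, fn=0))
        assert rep.accuracy == pytest.approx(190 / 209 * 100)
        assert rep.sensitivity == pytest.approx(1.0)
        assert rep.specificity == pytest.approx(115 / 134)

    def test_undefined_rates_reported_as_none(self):
        rep = metrics(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))
        assert rep.sensitivity is None
        assert rep.specificity == pytest.approx(0.5)

    def test_accuracy_decomposes_into_class_rates(self):
        c = ConfusionCounts(tp=30, tn=50, fp=10, fn=20)
        rep = metrics(c)
        n_pos, n_neg = c.tp + c.fn, c.tn + c.fp
        assert rep.accuracy / 100 == pytest.approx(
            (rep.sensitivity * n_pos + rep.specificity * n_neg) / c.total)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        curve, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_uninformative_scores(self):
        _, auc = roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        truth = rng.integers(0, 2, 60)
        truth[:2] = [0, 1]
        curve, _ = roc_auc(scores, truth)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_trapezoid_equals_pair_counting(self, data):
        """The threshold-sweep trapezoidal area is exactly the pair-counting
        statistic, including tied scores (midpoint convention)."""
        n = data.draw(st.integers(4, 60))
        # coarse score grid to force ties
        scores = data.draw(st.lists(
            st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]),
            min_size=n, max_size=n))
        truth = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(truth)) < 2:
            truth[0], truth[1] = 0, 1
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(pair_counting_auc(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


def _toy_table(n_pos, n_neg, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "status": ["MS"] * n_pos + ["control"] * n_neg,
        "x": rng.random(n_pos + n_neg),
    })


class TestRepeatedKfold:
    def test_grid_shape_and_fold_sizes(self):
        table = _toy_table(300, 300)
        sizes = []

        def pipe(train, test, fold_seed):
            sizes.append(len(test))
            return 100.0

        report = repeated_kfold(table, pipe, k=6, repeats=3, seed=0)
        assert report.cell_accuracy.shape == (3, 6)
        assert all(s == 100 for s in sizes)  # n=600, k=6 -> folds of 100
        assert report.mean == 100.0 and report.sd == 0.0 and report.robust

    def test_majority_rate_oracle_for_constant_predictor(self):
        """A pipeline that always predicts the majority class scores exactly
        the fold's majority-class rate, verified by direct counting."""
        table = _toy_table(80, 40, seed=1)
        recorded = []

        def pipe(train, test, fold_seed):
            maj = train["status"].value_counts().idxmax()
            acc = (test["status"] == maj).mean() * 100
            recorded.append(((test["status"] == "MS").sum(), len(test), acc))
            return acc

        report = repeated_kfold(table, pipe, k=4, repeats=2, seed=3)
        for (n_ms, n, acc), cell in zip(recorded,
                                        report.cell_accuracy.ravel()):
            assert cell == pytest.approx(n_ms / n * 100)
            assert acc == cell

    def test_stratification_keeps_both_classes(self):
        table = _toy_table(90, 12, seed=2)

        def pipe(train, test, fold_seed):
            assert set(test["status"]) == {"MS", "control"}
            return 50.0

        repeated_kfold(table, pipe, k=6, repeats=1, seed=0)

    def test_too_small_class_rejected(self):
        table = _toy_table(30, 4)
        with pytest.raises(ValueError, match="stratified"):
            repeated_kfold(table, lambda a, b, c: 0.0, k=6, repeats=1)

    def test_robustness_flag_uses_threshold(self):
        table = _toy_table(60, 60)
        accs = iter([50, 90, 50, 90, 50, 90] * 3)

        def pipe(train, test, fold_seed):
            return float(next(accs))

        report = repeated_kfold(table, pipe, k=6, repeats=3, seed=0,
                                robustness_sd_threshold=5.0)
        assert report.sd > 5.0
        assert not report.robust
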