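"""Metric closed forms, degenerate conventions, and rank statistics."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from il10pep import (ConfusionCounts, confusion, evaluate_scores, pr_ap,
                     roc_auc, scalar_metrics)
from il10pep.errors import MetricError, ValidationError
from il10pep.metrics import summarize_reports


class TestConfusion:
    def test_hand_case(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_all_predicted_positive(self):
        c = confusion([1, 0, 1], [1, 1, 1])
        assert c.tn == c.fn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion([1, 0], [1])

    def test_non_binary(self):
        with pytest.raises(ValidationError):
            confusion([1, 2], [1, 0])


class TestScalarMetrics:
    def test_perfect_classifier(self):
        r = scalar_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (r.accuracy, r.precision, r.recall, r.specificity, r.mcc) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        r = scalar_metrics(ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert r.accuracy == pytest.approx(0.8)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert r.specificity == pytest.approx(5 / 6)
        assert r.mcc == pytest.approx(14 / 24)

    def test_uninformative_symmetry(self):
        r = scalar_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert r.mcc == 0.0 and r.accuracy == 0.5

    def test_degenerate_denominators_return_zero_and_warn(self):
        with pytest.warns(RuntimeWarning, match="zero denominator"):
            r = scalar_metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=3))
        assert r.precision == 0.0 and r.specificity == 0.0 and r.mcc == 0.0

    def test_class_swap_leaves_accuracy_and_mcc_unchanged(self):
        c = ConfusionCounts(tp=30, tn=50, fp=10, fn=7)
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        a, b = scalar_metrics(c), scalar_metrics(swapped)
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.mcc == pytest.approx(b.mcc)


class TestRocAuc:
    def test_perfect_and_anti_ordering(self):
        y = [0, 0, 1, 1]
        assert roc_auc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc(y, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1
        s = rng.normal(size=200)
        assert abs(roc_auc(y, s) - 0.5) < 0.1

    def test_complement_property(self, rng):
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.normal(size=50)  # continuous, tie-free
        assert roc_auc(y, s) + roc_auc(y, -s) == pytest.approx(1.0)

    def test_matches_sklearn_with_ties(self, rng):
        y = rng.integers(0, 2, size=300)
        y[0], y[1] = 0, 1
        s = rng.integers(0, 8, size=300).astype(float)  # heavy ties
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert pr_ap([0, 1, 1], [0.1, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_prevalence(self):
        y = [1, 0, 0, 1, 0]
        assert pr_ap(y, [0.5] * 5) == pytest.approx(2 / 5)

    def test_hand_enumeration(self):
        # thresholds desc: P=1,R=1/2; P=1/2,R=1/2; P=2/3,R=1
        # AP = (1/2-0)*1 + 0*1/2 + (1-1/2)*2/3 = 5/6
        assert pr_ap([1, 0, 1], [0.9, 0.8, 0.7]) == pytest.approx(5 / 6)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=250)
        y[0], y[1] = 0, 1
        s = rng.normal(size=250)
        assert pr_ap(y, s) == pytest.approx(average_precision_score(y, s))

    def test_matches_sklearn_with_ties(self, rng):
        y = rng.integers(0, 2, size=250)
        y[0], y[1] = 0, 1
        s = rng.integers(0, 6, size=250).astype(float)
        assert pr_ap(y, s) == pytest.approx(average_precision_score(y, s))


class TestPermutationNulls:
    def test_mcc_near_zero_for_label_independent_predictions(self, rng):
        vals = []
        for _ in range(40):
            y = rng.integers(0, 2, size=500)
            p = rng.permutation(y)
            vals.append(scalar_metrics(confusion(y, p)).mcc)
        assert abs(np.mean(vals)) < 0.05


class TestReports:
    def test_evaluate_scores_full_report(self, rng):
        y = rng.integers(0, 2, size=100)
        y[0], y[1] = 0, 1
        s = rng.uniform(size=100)
        r = evaluate_scores(y, s)
        for m in ("accuracy", "precision", "recall", "specificity"):
            assert 0.0 <= getattr(r, m) <= 1.0
        assert -1.0 <= r.mcc <= 1.0
        assert 0.0 <= r.auc_roc <= 1.0 and 0.0 <= r.auc_pr <= 1.0

    def test_summarize_reports_mean_sd(self, rng):
        reports = []
        for _ in range(5):
            y = rng.integers(0, 2, size=60)
            y[0], y[1] = 0, 1
            reports.append(evaluate_scores(y, rng.uniform(size=60)))
        summary = summarize_reports(reports)
        for metric, (mean, sd) in summary.items():
            assert sd >= 0.0
        assert set(summary) == {"accuracy", "precision", "recall",
                                "specificity", "mcc", "auc_roc", "auc_pr"}
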