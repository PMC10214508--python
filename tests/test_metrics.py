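import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crankms import (
    ConfusionMatrix,
    MetricVector,
    aggregate,
    confusion,
    metric_vector,
    pooled_rsd,
    pr_curve_auc,
    roc_curve_auc,
)


def roc_auc_pair_counting(labels, scores):
    """Independent oracle: concordant pairs, ties counted 1/2."""
    labels = np.asarray(labels)
    pos = np.asarray(scores, dtype=float)[labels == 1]
    neg = np.asarray(scores, dtype=float)[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
    return total / (len(pos) * len(neg))


def pr_auc_threshold_sweep(labels, scores):
    """Independent oracle: explicit sweep over every distinct score."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    points = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        points.append((tp / (labels == 1).sum(), tp / pred.sum()))
    recall, precision = zip(*points)
    recall = (0.0,) + recall
    precision = (precision[0],) + precision
    return np.trapezoid(precision, recall)


class TestConfusion:
    def test_direct_count(self):
        cm = confusion([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_perfect_scores(self):
        cm = confusion([1, 0, 1], [0.99, 0.01, 0.98])
        assert cm.fn == cm.fp == 0

    def test_threshold_tie_predicts_positive(self):
        cm = confusion([1, 0], [0.5, 0.5], threshold=0.5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])


class TestMetricVector:
    def test_hand_computed_values(self):
        mv = metric_vector(ConfusionMatrix(tp=30, fn=5, fp=10, tn=30))
        assert mv.accuracy == pytest.approx(0.8)
        assert mv.precision == pytest.approx(0.75)
        assert mv.sensitivity == pytest.approx(30 / 35)
        assert mv.specificity == pytest.approx(0.75)
        assert mv.f1 == pytest.approx(0.8)
        assert mv.mcc == pytest.approx(850 / 1400)  # ~0.607

    def test_perfect_matrix_all_ones(self):
        mv = metric_vector(ConfusionMatrix(5, 0, 0, 5))
        assert (mv.accuracy, mv.precision, mv.sensitivity, mv.specificity, mv.f1, mv.mcc) \
            == (1, 1, 1, 1, 1, 1)

    def test_degenerate_all_positive_predictions(self):
        mv = metric_vector(ConfusionMatrix(tp=5, fn=0, fp=5, tn=0))
        assert mv.mcc == 0.0  # zero-denominator convention
        assert mv.specificity == 0.0  # TN/(TN+FP) = 0/5, defined

    def test_zero_denominator_metrics_undefined(self):
        # no predicted positives: precision 0/0 is undefined, not zero
        mv = metric_vector(ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
        assert math.isnan(mv.precision)
        assert mv.mcc == 0.0

    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_accuracy_decomposition_and_mcc_antisymmetry(self, counts):
        tp, fn, fp, tn = counts
        if tp + fn + fp + tn == 0:
            return
        cm = ConfusionMatrix(tp, fn, fp, tn)
        mv = metric_vector(cm)
        prevalence = (tp + fn) / cm.n
        if not (math.isnan(mv.sensitivity) or math.isnan(mv.specificity)):
            assert mv.accuracy == pytest.approx(
                prevalence * mv.sensitivity + (1 - prevalence) * mv.specificity
            )
        # flipping the true labels swaps tp<->fp and fn<->tn, negating MCC
        flipped = metric_vector(ConfusionMatrix(fp, tn, tp, fn))
        assert flipped.mcc == pytest.approx(-mv.mcc)


class TestROC:
    @pytest.mark.parametrize(
        "labels,scores,expected",
        [
            ([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2], 1.0),
            ([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2], 0.75),
            ([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9], 0.0),
        ],
    )
    def test_known_values(self, labels, scores, expected):
        _, auc = roc_curve_auc(labels, scores)
        assert auc == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([1, 1], [0.2, 0.3])

    def test_matches_pair_counting_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 31)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            curve, auc = roc_curve_auc(labels, scores)
            assert auc == pytest.approx(roc_auc_pair_counting(labels, scores))
            assert (np.diff(curve.points, axis=0) >= 0).all()  # monotone
            np.testing.assert_array_equal(curve.points[0], [0, 0])
            np.testing.assert_array_equal(curve.points[-1], [1, 1])


class TestPR:
    def test_perfect_separation(self):
        _, auc = pr_curve_auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2])
        assert auc == pytest.approx(1.0)

    @pytest.mark.parametrize("n_pos,n_neg", [(3, 9), (5, 5), (8, 2)])
    def test_constant_scores_give_prevalence(self, n_pos, n_neg):
        labels = [1] * n_pos + [0] * n_neg
        _, auc = pr_curve_auc(labels, [0.5] * (n_pos + n_neg))
        assert auc == pytest.approx(n_pos / (n_pos + n_neg))

    def test_no_positive_labels_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_auc([0, 0], [0.2, 0.3])

    def test_matches_threshold_sweep_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            labels = rng.integers(0, 2, size=20)
            labels[0] = 1
            scores = np.round(rng.random(20), 1)
            curve, auc = pr_curve_auc(labels, scores)
            assert auc == pytest.approx(pr_auc_threshold_sweep(labels, scores))
            recall = curve.points[:, 0]
            assert (np.diff(recall) >= 0).all() and recall[0] == 0 and recall[-1] == 1


class TestAggregation:
    def test_mean_and_sample_sd(self):
        rows = [MetricVector(accuracy=0.8), MetricVector(accuracy=1.0)]
        summary = aggregate(rows)
        assert summary.mean["accuracy"] == pytest.approx(0.9)
        assert summary.sd["accuracy"] == pytest.approx(0.14142, abs=1e-4)

    def test_constant_values_zero_sd(self):
        summary = aggregate([MetricVector(mcc=0.5)] * 5)
        assert summary.sd["mcc"] == 0.0

    def test_undefined_values_excluded_and_counted(self):
        rows = [
            MetricVector(precision=0.8),
            MetricVector(precision=math.nan),
            MetricVector(precision=1.0),
        ]
        summary = aggregate(rows)
        assert summary.mean["precision"] == pytest.approx(0.9)
        assert summary.n_undefined["precision"] == 1
        assert math.isnan(summary.mean["auc_roc"])  # undefined everywhere

    def test_pooled_rsd(self):
        rows = [
            MetricVector(accuracy=0.45, mcc=0.95),
            MetricVector(accuracy=0.55, mcc=1.05),
        ]
        summary = aggregate(rows)
        # accuracy: mean .5 sd ~.0707 -> 14.14%; mcc: mean 1.0 sd ~.0707 -> 7.07%
        expected = (summary.sd["accuracy"] / 0.5 + summary.sd["mcc"] / 1.0) / 2 * 100
        assert pooled_rsd(summary, metrics=("accuracy", "mcc")) == pytest.approx(expected)

    def test_pooled_rsd_single_metric_is_its_own_rsd(self):
        summary = aggregate([MetricVector(f1=0.4), MetricVector(f1=0.6)])
        assert pooled_rsd(summary, metrics=("f1",)) == pytest.approx(
            summary.sd["f1"] / 0.5 * 100
        )
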