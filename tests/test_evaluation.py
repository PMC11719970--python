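import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdeg.evaluation import (
    ConfusionCounts,
    binary_metrics,
    confusion,
    multiclass_metrics,
    roc_and_threshold,
)


class TestConfusion:
    def test_perfect(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 2)

    def test_mixed(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_single_sample(self):
        c = confusion([0], [1])
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_non_binary(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])


class TestBinaryMetrics:
    def test_formula_case(self):
        # direct formula evaluation: mcc = (2*2 - 1*1)/sqrt(3*3*3*3) = 3/9
        r = binary_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=2))
        assert r.accuracy == pytest.approx(4 / 6)
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(2 / 3)
        assert r.mcc == pytest.approx(1 / 3)

    def test_perfect(self):
        r = binary_metrics(ConfusionCounts(tp=3, fp=0, fn=0, tn=4))
        assert (r.accuracy, r.precision, r.recall, r.f1, r.mcc) == (1, 1, 1, 1, 1)
        assert r.degenerate == ()

    def test_degenerate_all_negative_predictions(self):
        r = binary_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=3))
        assert r.precision == 0.0
        assert r.mcc == 0.0
        assert "precision" in r.degenerate and "mcc" in r.degenerate

    def test_f1_harmonic_mean(self):
        r = binary_metrics(ConfusionCounts(tp=3, fp=2, fn=1, tn=4))
        expected = 2 * r.precision * r.recall / (r.precision + r.recall)
        assert r.f1 == pytest.approx(expected)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_mcc_range_and_sign_flip(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        r = binary_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        assert -1.0 <= r.mcc <= 1.0
        # inverting predictions swaps tp<->fn and fp<->tn columns
        r_inv = binary_metrics(ConfusionCounts(tp=fn, fp=tn, fn=tp, tn=fp))
        if "mcc" not in r.degenerate and "mcc" not in r_inv.degenerate:
            assert r_inv.mcc == pytest.approx(-r.mcc)

    def test_mcc_one_iff_no_errors(self):
        r = binary_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert r.mcc == 1.0
        r2 = binary_metrics(ConfusionCounts(tp=5, fp=1, fn=0, tn=4))
        assert r2.mcc < 1.0


class TestMulticlassMetrics:
    def test_perfect(self):
        r = multiclass_metrics(list("ABCD"), list("ABCD"), list("ABCD"))
        assert (r.accuracy, r.precision, r.recall, r.f1) == (1, 1, 1, 1)

    def test_hand_enumeration(self):
        # per-class OvR: A: tp=1 fp=1 -> prec 0.5; B: tp=1 fp=1 -> prec 0.5
        r = multiclass_metrics(["A", "A", "B", "B"], ["A", "B", "A", "B"], ["A", "B"])
        assert r.accuracy == pytest.approx(0.5)
        assert r.precision == pytest.approx(0.5)

    def test_single_class_truth(self):
        r = multiclass_metrics(["A", "A"], ["A", "A"], ["A", "B"])
        assert r.accuracy == 1.0
        assert any(flag.startswith(("precision[B", "recall[B")) for flag in r.degenerate)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            multiclass_metrics(["A"], ["Z"], ["A", "B"])

    def test_accuracy_equals_confusion_trace(self):
        rng = np.random.default_rng(5)
        classes = list("ABCD")
        t = rng.choice(classes, 100)
        p = rng.choice(classes, 100)
        r = multiclass_metrics(t, p, classes)
        trace = sum(
            np.sum((t == c) & (p == c)) for c in classes
        )
        assert r.accuracy == pytest.approx(trace / 100)


def brute_force_best_j(scores, y):
    """Independent oracle: TPR-FPR is piecewise constant, so evaluating at
    every candidate threshold (all midpoints and beyond-range values) finds
    the global maximum."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    cands = np.concatenate([[scores.min() - 1], np.unique(scores), [scores.max() + 1],
                            (np.sort(np.unique(scores))[:-1] + np.sort(np.unique(scores))[1:]) / 2
                            if len(np.unique(scores)) > 1 else []])
    best = -np.inf
    for thr in cands:
        pred = scores > thr
        tpr = np.sum(pred & (y == 1)) / np.sum(y == 1)
        fpr = np.sum(pred & (y == 0)) / np.sum(y == 0)
        best = max(best, tpr - fpr)
    return best


class TestRocThreshold:
    def test_separable(self):
        res = roc_and_threshold([0.2, 0.3, 0.7, 0.8], [0, 0, 1, 1])
        assert res.threshold == pytest.approx(0.5)
        assert res.j == pytest.approx(1.0)

    def test_all_equal_scores(self):
        res = roc_and_threshold([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert res.j == 0.0
        assert res.threshold == pytest.approx(1.0)  # above-max sentinel, clipped

    def test_anticorrelated_never_negative(self):
        res = roc_and_threshold([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        assert res.j == pytest.approx(0.0)
        assert res.j >= 0.0

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_and_threshold([0.1, 0.9], [1, 1])

    def test_matches_brute_force_small(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.uniform(0, 1, size=n), 2)
            res = roc_and_threshold(scores, y)
            assert res.j == pytest.approx(brute_force_best_j(scores, y), abs=1e-12)
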