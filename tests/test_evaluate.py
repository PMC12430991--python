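"""Metrics: confusion/classification arithmetic, ROC/AUC oracle, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrstress import (
    ConfusionMatrix,
    class_metrics,
    confusion,
    pearson,
    roc_ovr,
    summary_stats,
)

# Binary wearable validation matrix reconstructed from the reported counts:
# 4720 baseline correct, 2403 stress correct, 289 stress->baseline errors,
# zero false positives (stress precision 1.00). Rows = true, cols = predicted.
WESAD_CM = ConfusionMatrix(labels=("baseline", "stress"),
                           counts=np.array([[4720, 0], [289, 2403]]))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "c", "a", "b"] * 2
        cm = confusion(y, y, labels=("a", "b", "c"))
        assert cm.total == 10
        assert np.trace(cm.counts) == 10

    def test_wearable_counts_total(self):
        assert WESAD_CM.total == 7412
        assert WESAD_CM.counts.sum(axis=1).tolist() == [4720, 2692]

    def test_empty_input(self):
        cm = confusion([], [], labels=("a", "b"))
        assert cm.total == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(["a"], ["a", "b"], labels=("a", "b"))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a", "x"], ["a", "a"], labels=("a", "b"))


class TestClassMetrics:
    def test_wearable_arithmetic(self):
        """Accuracy 96%, stress precision 1.00 / recall 0.89, F1 0.97/0.94."""
        m = class_metrics(WESAD_CM)
        assert m.accuracy == pytest.approx(7123 / 7412)
        assert round(m.accuracy * 100) == 96
        assert m.precision["stress"] == pytest.approx(1.00)
        assert m.recall["stress"] == pytest.approx(2403 / 2692)
        assert round(m.recall["stress"], 2) == 0.89
        assert round(m.f1["stress"], 2) == 0.94
        assert round(m.f1["baseline"], 2) == 0.97

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            cm = ConfusionMatrix(labels=("a", "b", "c"),
                                 counts=rng.integers(0, 50, (3, 3)))
            if cm.total == 0:
                continue
            m = class_metrics(cm)
            for lab in cm.labels:
                p, r, f = m.precision[lab], m.recall[lab], m.f1[lab]
                assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_label_permutation_consistency(self):
        cm = ConfusionMatrix(labels=("a", "b"), counts=np.array([[8, 2], [3, 7]]))
        perm = ConfusionMatrix(labels=("b", "a"), counts=np.array([[7, 3], [2, 8]]))
        m, mp = class_metrics(cm), class_metrics(perm)
        assert m.accuracy == mp.accuracy
        assert m.precision["a"] == mp.precision["a"]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(ConfusionMatrix(labels=("a",), counts=np.zeros((1, 1))))


def mann_whitney_auc(scores, positive):
    """Rank-statistic oracle: (pairs won + half ties) / (n1 * n0)."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        y = ["s"] * 5 + ["b"] * 5
        res = roc_ovr({"s": np.arange(10, 0, -1)}, y, labels=("s",))
        assert res.auc["s"] == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        y = ["s"] * 5 + ["b"] * 5
        res = roc_ovr({"s": np.zeros(10)}, y, labels=("s",))
        assert res.auc["s"] == pytest.approx(0.5)

    def test_single_class_truth_undefined(self):
        res = roc_ovr({"s": np.arange(4.0)}, ["s"] * 4, labels=("s",))
        assert res.auc["s"] is None

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.choice(["s", "b"], n).tolist()
            if len(set(y)) < 2:
                continue
            res = roc_ovr({"s": scores}, y, labels=("s",))
            oracle = mann_whitney_auc(scores, np.array(y) == "s")
            assert res.auc["s"] == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        y = rng.choice([0, 1], 60)
        res = roc_ovr({1: scores}, y.tolist(), labels=(1,))
        assert res.auc[1] == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=50)
        y = rng.choice(["s", "b"], 50).tolist()
        res = roc_ovr({"s": scores}, y, labels=("s",))
        fpr, tpr = res.points["s"]
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_fixture_bruteforce(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 6], dtype=float)
        r, p = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_brute = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert r == pytest.approx(r_brute, abs=1e-12)
        # p from the t transform with n-2 dof
        from scipy.stats import t as tdist
        tval = r_brute * np.sqrt(3) / np.sqrt(1 - r_brute**2)
        assert p == pytest.approx(2 * tdist.sf(abs(tval), 3), rel=1e-9)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=25)
    def test_affine_invariance(self, a, b):
        x = np.array([0.5, 1.1, 1.9, 3.2, 4.0, 5.5])
        y = np.array([2.0, 1.0, 3.5, 2.5, 5.0, 4.5])
        r0, _ = pearson(x, y)
        r1, _ = pearson(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummaryStats:
    def test_odd_and_even_medians(self):
        s = summary_stats([1, 2, 3])
        assert (s.median, s.mean) == (2.0, 2.0)
        assert summary_stats([1, 2, 3, 4]).median == 2.5

    def test_constant_has_zero_iqr(self):
        s = summary_stats([5.0] * 7)
        assert s.iqr == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summary_stats([])
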