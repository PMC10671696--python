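"""Diagnostic-performance statistics against independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fhdx.evaluation import (
    ConfusionMatrix,
    confusion,
    fisher_exact,
    metrics,
    reconstruct_confusion,
    roc,
    round_half_up_percent,
    youden_optimal,
)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (Fraction(22, 26), 84.6),
            (Fraction(1, 3), 33.3),
            (Fraction(2, 6), 33.3),
            (Fraction(845, 1000), 84.5),   # exact half rounds up
            (Fraction(5, 9), 55.6),
            (0.5, 50.0),
        ],
    )
    def test_half_up_percent(self, value, expected):
        assert round_half_up_percent(value) == expected


class TestConfusion:
    def test_hand_count(self):
        cm, excl = confusion([True, True, False], [True, False, False])
        assert (cm.tp, cm.fn, cm.tn, cm.fp, excl) == (1, 1, 1, 0, 0)

    def test_all_correct(self):
        cm, _ = confusion([True, False], [True, False])
        assert cm.fn == cm.fp == 0

    def test_missing_calls_excluded_and_counted(self):
        cm, excl = confusion([True, True, False], [True, None, False])
        assert cm.n == 2 and excl == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=2)


class TestMetrics:
    def test_published_row_pattern(self):
        m = metrics(ConfusionMatrix(tp=22, fp=3, fn=4, tn=2)).as_percent()
        assert m == {
            "sensitivity": 84.6, "specificity": 40.0, "ppv": 88.0,
            "npv": 33.3, "accuracy": 77.4, "prevalence": 83.9,
        }

    def test_high_performance_row_pattern(self):
        m = metrics(ConfusionMatrix(tp=23, fp=1, fn=1, tn=4)).as_percent()
        assert m["sensitivity"] == 95.8 and m["accuracy"] == 93.1

    def test_degenerate_all_negative(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5)).as_percent()
        assert m["specificity"] == 100.0 and m["sensitivity"] is None

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_bayes_identity_for_ppv(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0 or tp + fp == 0:
            return
        m = metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        se, sp, prev = m.sensitivity, m.specificity, m.prevalence
        ppv_bayes = (se * prev) / (se * prev + (1 - sp) * (1 - prev))
        assert ppv_bayes == m.ppv  # exact fraction arithmetic

    def test_invariant_under_reordering(self):
        truth = [True, False, True, True, False]
        calls = [True, True, False, True, False]
        cm1, _ = confusion(truth, calls)
        order = [3, 0, 4, 1, 2]
        cm2, _ = confusion([truth[i] for i in order], [calls[i] for i in order])
        assert metrics(cm1) == metrics(cm2)


def _fisher_enumeration(table):
    """Independent oracle: enumerate all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        # same relative guard scipy applies for float-equal probabilities
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[12, 4], [0, 3]], 0.036),   # family pCVD 75.0% vs 0.0%
            ([[18, 8], [0, 5]], 0.008),   # family pCVD 69.2% vs 0.0%
            ([[1, 1], [1, 1]], 1.0),
        ],
    )
    def test_published_pvalues(self, table, expected):
        assert round(fisher_exact(table), 3) == expected

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact(table) == pytest.approx(
            _fisher_enumeration(table), abs=1e-9
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == 1.0 and curve.youden_j == 1.0

    def test_constant_score(self):
        curve = roc([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert curve.auc == 0.5 and curve.youden_j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [True, True, True])

    @given(seed=st.integers(0, 200))
    def test_trapezoid_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            return
        scores = np.round(rng.normal(truth * 1.0, 1.0), int(rng.integers(0, 3)))
        curve = roc(scores, truth)
        d = np.subtract.outer(scores[truth], scores[~truth])
        pairwise = (d > 0).mean() + 0.5 * (d == 0).mean()
        assert curve.auc == pytest.approx(pairwise, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        truth = rng.random(50) < 0.4
        truth[0], truth[1] = True, False
        scores = rng.normal(truth * 1.0, 1.0)
        a1 = roc(scores, truth).auc
        a2 = roc(np.exp(3 * scores), truth).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sklearn_auc(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        truth = rng.random(80) < 0.5
        truth[0], truth[1] = True, False
        scores = rng.normal(truth * 2.0, 1.5)
        assert roc(scores, truth).auc == pytest.approx(
            sklearn.roc_auc_score(truth, scores), abs=1e-12
        )

    @given(seed=st.integers(0, 100))
    def test_youden_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.random(25) < 0.5
        if truth.all() or not truth.any():
            return
        scores = np.round(rng.normal(truth * 1.0, 1.0), 1)
        curve = roc(scores, truth)
        threshold, j = youden_optimal(curve)
        brute = max(
            (scores[truth] >= c).mean() + (scores[~truth] < c).mean() - 1
            for c in curve.thresholds
        )
        assert j == pytest.approx(brute, abs=1e-12)
        # reported threshold attains the reported J
        se = (scores[truth] >= threshold).mean()
        sp = (scores[~truth] < threshold).mean()
        assert se + sp - 1 == pytest.approx(j, abs=1e-12)


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "targets, smallest",
        [
            ({"sensitivity": 84.6, "specificity": 40.0, "ppv": 88.0, "npv": 33.3},
             (22, 3, 4, 2)),
            ({"sensitivity": 95.8, "specificity": 80.0, "ppv": 95.8, "npv": 80.0},
             (23, 1, 1, 4)),
            ({"sensitivity": 100.0, "specificity": 100.0}, (1, 0, 0, 1)),
        ],
    )
    def test_smallest_solutions(self, targets, smallest):
        sols = reconstruct_confusion(targets, n_max=60 if len(targets) > 2 else 2)
        cm = sols[0]
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == smallest

    def test_needs_two_metrics(self):
        with pytest.raises(ValueError):
            reconstruct_confusion({"sensitivity": 90.0})

    @settings(max_examples=25)
    @given(
        tp=st.integers(1, 12), fp=st.integers(0, 12),
        fn=st.integers(0, 12), tn=st.integers(1, 12),
    )
    def test_roundtrip_contains_generating_matrix(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        rounded = {
            k: v
            for k, v in metrics(cm).as_percent().items()
            if v is not None and k in ("sensitivity", "specificity", "ppv", "npv")
        }
        if len(rounded) < 2:
            return
        assert cm in reconstruct_confusion(rounded, n_max=cm.n)
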