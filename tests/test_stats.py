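"""2x2 machinery, exact tests against enumeration oracles, ROC selection."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancyst.stats import (
    ConfusionTable,
    MwMethod,
    confusion,
    fisher_exact_2x2,
    mann_whitney_exact,
    roc_threshold,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (integer arithmetic).

    All tables with the observed margins share the denominator C(n, r1), so
    tables are compared by integer numerators: p sums the probabilities of
    those whose probability does not exceed the observed table's.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    def weight(k):
        return comb(c1, k) * comb(n - c1, r1 - k)
    observed = weight(a)
    total = comb(n, r1)
    acc = sum(w for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
              if (w := weight(k)) <= observed)
    return acc / total


def mw_oracle(x, y):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    n1 = len(x)

    def u_of(sample):
        r = sum(ranks[v] for v in sample)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(x)
    mean_u = n1 * len(y) / 2
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_of(list(combo)) - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestConfusion:
    def test_surgical_style_counts_give_one_decimal_percent(self):
        tab = ConfusionTable(tp=32, fp=1, fn=4, tn=9)
        assert tab.sensitivity == 88.9       # 32/36
        assert tab.specificity == 90.0       # 9/10
        assert tab.ppv == 97.0               # 32/33
        assert tab.npv == 69.2               # 9/13

    def test_perfect_agreement(self):
        tab = confusion(["m", "n", "m"], ["m", "n", "m"], positive="m")
        assert tab.sensitivity == 100.0 and tab.specificity == 100.0

    def test_degenerate_denominators_are_reported_missing(self):
        tab = confusion(["m", "m"], ["m", "n"], positive="m")
        assert tab.specificity == 0.0
        assert tab.npv is None

    def test_swapping_positive_label_swaps_metric_pairs(self):
        pred = ["m", "m", "n", "m", "n", "n", "m"]
        truth = ["m", "n", "n", "m", "m", "n", "n"]
        t_m = confusion(pred, truth, positive="m")
        t_n = confusion(pred, truth, positive="n")
        assert (t_m.sensitivity, t_m.specificity) == (t_n.specificity, t_n.sensitivity)
        assert (t_m.ppv, t_m.npv) == (t_n.npv, t_n.ppv)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["m"], ["m", "n"], positive="m")


class TestFisher:
    @pytest.mark.parametrize("table, expected", [
        ([[1, 9], [11, 3]], 0.0027594561852200836),
        ([[5, 5], [5, 5]], 1.0),
    ])
    def test_frozen_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-7)

    def test_molecular_vs_cytology_table_is_highly_significant(self):
        p = fisher_exact_2x2([[32, 4], [15, 21]])
        assert p <= 1e-4
        assert p == pytest.approx(fisher_oracle(32, 4, 15, 21), rel=1e-7)

    @settings(derandomize=True, max_examples=300)
    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
    def test_agrees_with_enumeration_oracle(self, cells):
        a, b, c, d = cells
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 15)] * 4).filter(lambda t: sum(t) > 0))
    def test_invariant_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        p, method = mann_whitney_exact([1.0, 2.5, 3.5], [1.5, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        assert method == MwMethod.EXACT

    def test_fully_separated_triplets(self):
        p, _ = mann_whitney_exact([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_agrees_with_permutation_oracle_on_random_small_samples(self):
        rng = np.random.default_rng(20240917)
        for _ in range(50):
            n1, n2 = rng.integers(2, 6, size=2)
            pooled = rng.permutation(rng.normal(size=n1 + n2))
            x, y = list(pooled[:n1]), list(pooled[n1:])
            p, method = mann_whitney_exact(x, y)
            assert method == MwMethod.EXACT
            assert p == pytest.approx(mw_oracle(x, y), abs=1e-10)

    def test_large_or_tied_samples_fall_back_to_normal_approximation(self):
        p, method = mann_whitney_exact(list(range(20)), list(range(10, 30)))
        assert method == MwMethod.NORMAL_APPROX
        p_tied, method_tied = mann_whitney_exact([1, 1, 2], [2, 3, 3])
        assert method_tied == MwMethod.NORMAL_APPROX
        assert 0 < p <= 1 and 0 < p_tied <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.3, 5.0, 6.0, 7.0]
        labels = [0, 0, 0, 1, 1, 1]
        res = roc_threshold(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert 0.3 < res.optimal_threshold < 5.0
        assert res.youden_index == pytest.approx(1.0)

    def test_ties_break_toward_the_lowest_threshold(self):
        # scores where two thresholds achieve the same Youden index
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 1, 0, 1]
        res = roc_threshold(scores, labels)
        candidates = [t for t, s, p in res.points
                      if s + p - 1 == pytest.approx(res.youden_index)]
        assert res.optimal_threshold == min(candidates)

    def test_random_scores_have_auc_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        res = roc_threshold(list(scores), list(labels))
        assert abs(res.auc - 0.5) < 0.1

    def test_optimal_threshold_matches_brute_force_argmax(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        labels = np.array([0] * 40 + [1] * 40)
        res = roc_threshold(list(scores), list(labels))
        # independent brute force over every achievable operating point
        best = -np.inf
        for t in np.concatenate([[-np.inf], np.sort(scores), [np.inf]]):
            pred = scores >= t
            sens = (pred & (labels == 1)).sum() / 40
            spec = (~pred & (labels == 0)).sum() / 40
            best = max(best, sens + spec - 1)
        assert res.youden_index == pytest.approx(best)

    def test_auc_equals_mann_whitney_u_statistic_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.0, size=30)   # positives
        y = rng.normal(0.0, 1.0, size=25)   # negatives
        res = roc_threshold(list(x) + list(y), [1] * 30 + [0] * 25)
        u = sum((xi > yj) for xi in x for yj in y)
        assert res.auc == pytest.approx(u / (30 * 25))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold([1.0, 2.0], [1, 1])
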