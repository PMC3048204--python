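"""ROC/AUC machinery: confusion matrices, pair-counting AUC vs trapezoidal
area, DeLong-type CI and paired comparison, best-accuracy cutoff search."""

import numpy as np
import pytest

from roma_dx.performance import (
    auc_confidence_interval,
    auc_mann_whitney,
    compare_paired_aucs,
    confusion_at_cutoff,
    find_ideal_cutoff,
    roc_curve,
    sensitivity_specificity_at,
)

MAL = [True, True, True]
BEN = [False, False, False]


def brute_force_auc(cases, controls):
    """Pair enumeration: P(case > control) + 0.5 P(tie)."""
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


def brute_force_best_cutoff(scores, labels):
    """Exhaustive accuracy maximization over distinct scores + inf sentinel,
    ties by Youden then smaller cutoff."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best = None
    for c in sorted(set(scores)) + [np.inf]:
        pos = scores >= c
        tp, fp = (pos & y).sum(), (pos & ~y).sum()
        fn, tn = (~pos & y).sum(), (~pos & ~y).sum()
        acc = (tp + tn) / len(scores)
        youden = tp / y.sum() + tn / (~y).sum() - 1
        key = (-acc, -youden, c)
        if best is None or key < best[0]:
            best = (key, c, acc)
    return best[1], best[2]


class TestConfusion:
    def test_toy_counts(self):
        scores = [100, 200, 300, 10, 20, 400]
        labels = MAL + BEN
        cm = confusion_at_cutoff(scores, labels, 50)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 1, 2, 0)
        assert sensitivity_specificity_at(scores, labels, 50) == pytest.approx((100.0, 200 / 3))

    def test_cutoff_above_max(self):
        cm = confusion_at_cutoff([1, 2, 3, 4], [True, True, False, False], 100)
        assert (cm.tp, cm.fp) == (0, 0)

    def test_cutoff_below_min_is_all_positive(self):
        sens, spec = sensitivity_specificity_at([1, 2, 3, 4], [True, True, False, False], 0)
        assert (sens, spec) == (100.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="benign"):
            confusion_at_cutoff([1, 2], [True, True], 1)
        with pytest.raises(ValueError, match="malignant"):
            confusion_at_cutoff([1, 2], [False, False], 1)

    def test_random_instances_vs_per_subject_count(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 10, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            c = float(rng.choice(scores))
            cm = confusion_at_cutoff(scores, labels, c)
            assert cm.tp == sum(s >= c for s, l in zip(scores, labels) if l)
            assert cm.fp == sum(s >= c for s, l in zip(scores, labels) if not l)
            assert cm.n == n


class TestAuc:
    def test_perfect_separation(self):
        est = auc_mann_whitney([10, 11, 1, 2], [True, True, False, False])
        assert est.auc == 1.0

    def test_all_ties(self):
        est = auc_mann_whitney([5, 5, 5, 5], [True, True, False, False])
        assert est.auc == 0.5

    def test_pair_enumeration_example(self):
        # cases {2,3}, controls {1,2}: wins 3.5 of 4 pairs
        est = auc_mann_whitney([2, 3, 1, 2], [True, True, False, False])
        assert est.auc == pytest.approx(3.5 / 4)

    def test_matches_brute_force_and_trapezoid(self, rng):
        """Pair counting == brute force == trapezoidal ROC area (<=1e-12)."""
        for _ in range(100):
            n1, n0 = int(rng.integers(2, 20)), int(rng.integers(2, 20))
            cases = rng.integers(0, 8, n1).astype(float)  # many ties
            controls = rng.integers(0, 8, n0).astype(float)
            scores = np.concatenate([cases, controls])
            labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
            auc = auc_mann_whitney(scores, labels).auc
            assert auc == pytest.approx(brute_force_auc(cases, controls), abs=1e-12)
            assert auc == pytest.approx(roc_curve(scores, labels).trapezoidal_auc(), abs=1e-12)

    def test_label_swap_mirrors_auc(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        a = auc_confidence_interval(scores, labels)
        b = auc_confidence_interval(scores, ~labels)
        assert b.auc == pytest.approx(1 - a.auc, abs=1e-12)
        assert b.ci_low == pytest.approx(1 - a.ci_high, abs=1e-12)
        assert b.ci_high == pytest.approx(1 - a.ci_low, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.lognormal(size=50)
        labels = rng.random(50) < 0.4
        a = auc_mann_whitney(scores, labels).auc
        assert auc_mann_whitney(np.log(scores), labels).auc == pytest.approx(a, abs=1e-12)
        assert auc_mann_whitney(scores**3, labels).auc == pytest.approx(a, abs=1e-12)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        assert auc_mann_whitney(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestRocCurve:
    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.integers(0, 5, 30).astype(float)
        labels = np.r_[np.ones(10, bool), np.zeros(20, bool)]
        curve = roc_curve(scores, labels)
        assert (curve.sens[0], curve.one_minus_spec[0]) == (0.0, 0.0)
        assert (curve.sens[-1], curve.one_minus_spec[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.sens) >= 0)
        assert np.all(np.diff(curve.one_minus_spec) >= 0)
        assert np.all(np.diff(curve.thresholds) < 0)


class TestCi:
    def test_degenerate_perfect_auc_flagged(self):
        est = auc_confidence_interval([10, 11, 1, 2], [True, True, False, False])
        assert est.auc == 1.0
        assert (est.ci_low, est.ci_high) == (1.0, 1.0)
        assert est.degenerate

    def test_ci_brackets_and_clips(self, rng):
        scores = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        est = auc_confidence_interval(scores, labels)
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0
        assert not est.degenerate


class TestPairedComparison:
    def test_identical_markers_give_p_one(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        res = compare_paired_aucs(scores, scores.copy(), labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(size=50)
        b = a + rng.normal(scale=0.5, size=50)
        labels = np.r_[np.ones(20, bool), np.zeros(30, bool)]
        r1 = compare_paired_aucs(a, b, labels)
        r2 = compare_paired_aucs(b, a, labels)
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-15)
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            compare_paired_aucs([1, 2, 3], [1, 2], [True, False, True])

    def test_clear_difference_detected(self, rng):
        n = 200
        labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        signal = np.r_[rng.normal(2.0, 1, n), rng.normal(0, 1, n)]
        noise = rng.normal(size=2 * n)
        res = compare_paired_aucs(signal, noise, labels)
        assert res.p < 0.001
        assert res.delta > 0


class TestIdealCutoff:
    def test_toy_instance(self):
        scores = [100, 200, 300, 10, 20, 400]
        labels = MAL + BEN
        res = find_ideal_cutoff(scores, labels)
        assert res.cutoff == 100
        assert res.accuracy == pytest.approx(5 / 6)
        assert res.sensitivity == pytest.approx(100.0)
        assert res.specificity == pytest.approx(200 / 3)

    def test_separated_classes(self):
        res = find_ideal_cutoff([5, 6, 7, 1, 2, 3], MAL + BEN)
        assert res.cutoff == 5.0
        assert res.accuracy == 1.0

    def test_matches_brute_force_on_random_instances(self, rng):
        """Exhaustive-search equivalence on 1,000 random tied instances."""
        for _ in range(1000):
            n = int(rng.integers(4, 25))
            scores = rng.integers(0, 6, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = find_ideal_cutoff(scores, labels)
            cutoff, acc = brute_force_best_cutoff(scores, labels)
            assert res.cutoff == cutoff
            assert res.accuracy == pytest.approx(acc, abs=1e-12)

    def test_consistent_with_confusion_matrix(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        res = find_ideal_cutoff(scores, labels)
        sens, spec = sensitivity_specificity_at(scores, labels, res.cutoff)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)
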