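import math

import numpy as np
import pytest

from adipomets.age_reference import fit_median_curve
from adipomets.roc_diagnostics import (
    delong_paired_test, delong_placements, diagnostic_metrics,
    evaluate_index, roc_curve, youden_cutoff,
)


def mann_whitney_auc(scores, labels):
    """Brute-force tie-corrected pairwise oracle."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestROCCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = roc_curve(np.ones(20), [0, 1] * 10)
        assert roc.auc == pytest.approx(0.5, abs=1e-15)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 200))
            scores = np.round(rng.normal(size=n), 1)  # rounded to force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            roc = roc_curve(scores, labels)
            assert abs(roc.auc - mann_whitney_auc(scores, labels)) < 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = np.round(rng.normal(size=300), 1)
        labels = rng.integers(0, 2, 300)
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        scores = np.exp(rng.normal(size=150))
        labels = rng.integers(0, 2, 150)
        base = roc_curve(scores, labels).auc
        assert roc_curve(np.log(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_curve(3 * scores + 7, labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            roc_curve([1.0, 2.0], [1, 1])

    def test_ci_covers_half_for_uninformative_score(self, rng):
        """A score independent of the labels: the DeLong 95% CI should
        contain 0.5 in roughly 95% of replicates."""
        covered = 0
        reps = 500
        for _ in range(reps):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, 200)
            if labels.sum() in (0, 200):
                labels[0] = 1 - labels[0]
            lo, hi = roc_curve(scores, labels).auc_ci95
            covered += lo <= 0.5 <= hi
        assert covered / reps >= 0.93


class TestDeLong:
    def test_placements_average_to_auc(self, rng):
        scores = np.round(rng.normal(size=120), 1)
        labels = rng.integers(0, 2, 120)
        auc, v10, v01 = delong_placements(scores, labels)
        assert v10.mean() == pytest.approx(auc, abs=1e-12)
        assert v01.mean() == pytest.approx(auc, abs=1e-12)

    def test_identical_scores_give_null_result(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        cmp_ = delong_paired_test(scores, scores, labels)
        assert cmp_.delta_auc == 0.0
        assert cmp_.z == 0.0
        assert cmp_.p == 1.0

    def test_variance_matches_jackknife(self, rng):
        """DeLong's analytic variance should track the leave-one-out
        jackknife variance of the AUC within 10%."""
        scores = rng.normal(size=100) + 0.8 * rng.integers(0, 2, 100)
        labels = rng.integers(0, 2, 100)
        roc = roc_curve(scores, labels)
        n = len(scores)
        loo = np.empty(n)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            loo[i] = mann_whitney_auc(scores[mask], labels[mask])
        jack = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert roc.auc_var == pytest.approx(jack, rel=0.10)

    def test_mismatched_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="same subjects"):
            delong_paired_test(rng.normal(size=30), rng.normal(size=31),
                               rng.integers(0, 2, 30))


class TestYouden:
    def test_perfect_separation_returns_smallest_positive_score(self):
        cutoff, j, se, sp = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.8)
        assert se == 1.0 and sp == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=50), 1)
            labels = rng.integers(0, 2, 50)
            if labels.sum() in (0, 50):
                labels[0] = 1 - labels[0]
            cutoff, j, _, _ = youden_cutoff(scores, labels)
            y = labels.astype(bool)
            best_j, best_t = -np.inf, None
            for t in np.unique(scores):  # ascending: first max = smallest cutoff
                se = np.mean(scores[y] >= t)
                sp = np.mean(scores[~y] < t)
                if se + sp - 1 > best_j + 1e-12:
                    best_j, best_t = se + sp - 1, t
            assert j == pytest.approx(best_j, abs=1e-12)
            assert cutoff == pytest.approx(best_t)

    def test_uninformative_scores_give_small_j(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        _, j, _, _ = youden_cutoff(scores, labels)
        assert 0.0 <= j < 0.08


class TestDiagnosticMetrics:
    # printed screening-table rows: (se, sp) with prevalence 917/1528
    @pytest.mark.parametrize("se,sp,ppv,npv,plr,nlr", [
        (0.224, 0.882, 74.0, 43.1, 1.90, 0.88),   # BMI
        (0.630, 0.604, 70.5, 52.1, 1.59, 0.61),   # WtHR
    ])
    def test_reference_rows(self, se, sp, ppv, npv, plr, nlr):
        m = diagnostic_metrics(se, sp, 917 / 1528)
        assert 100 * m.ppv == pytest.approx(ppv, abs=0.05)
        assert 100 * m.npv == pytest.approx(npv, abs=0.05)
        assert m.plr == pytest.approx(plr, abs=0.005)
        assert m.nlr == pytest.approx(nlr, abs=0.005)

    def test_uninformative_test(self):
        m = diagnostic_metrics(0.5, 0.5, 0.3)
        assert m.plr == pytest.approx(1.0)
        assert m.nlr == pytest.approx(1.0)
        assert m.ppv == pytest.approx(0.3)

    def test_bayes_bookkeeping(self, rng):
        for _ in range(50):
            se, sp, pi = rng.uniform(0.05, 0.95, 3)
            m = diagnostic_metrics(se, sp, pi)
            assert m.ppv * m.flagged_fraction == pytest.approx(se * pi, abs=1e-12)

    def test_degenerate_specificity_signalled(self):
        assert math.isinf(diagnostic_metrics(0.5, 1.0, 0.5).plr)
        assert math.isinf(diagnostic_metrics(0.5, 0.0, 0.5).nlr)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="se"):
            diagnostic_metrics(1.2, 0.5, 0.5)


class TestEvaluateIndex:
    def test_flagged_fraction_identity_equals_empirical(self, rng):
        ages = rng.uniform(18, 83, 600)
        values = np.exp(np.log(40) + 0.12 * rng.normal(size=600))
        labels = rng.uniform(size=600) < 0.5 + 0.3 * np.tanh(np.log(values / 40))
        model = fit_median_curve(values, ages, index_name="bmi")
        ev = evaluate_index(values, ages, labels, model, age_grid=np.arange(20, 81.0))
        assert ev.flagged_fraction_identity == pytest.approx(
            ev.flagged_fraction_empirical, abs=1e-12)
        assert ev.threshold_curve is not None
        assert np.all(ev.threshold_curve.cutoffs > 0)

    def test_auc_on_z_equals_auc_on_raw_within_single_age(self, rng):
        """Standardization is strictly increasing at fixed age, so the ROC
        is unchanged on a single-age slice."""
        ages = np.full(400, 55.0)
        values = np.exp(rng.normal(3.0, 0.3, 400))
        labels = rng.integers(0, 2, 400)
        train_v, train_a = np.exp(rng.normal(3.0, 0.3, 500)), rng.uniform(18, 83, 500)
        model = fit_median_curve(train_v, train_a)
        z = model.standardize(values, ages)
        assert roc_curve(z, labels).auc == pytest.approx(
            roc_curve(values, labels).auc, abs=1e-12)
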