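"""Classification metrics, fold statistics and cohort-table tests."""

import numpy as np
import pytest
from scipy import integrate, stats

from dosederm import tables
from dosederm.metrics import (
    MetricReport,
    SummaryPair,
    auc,
    brier_score,
    chi_square_2xk,
    cohens_d,
    confusion_metrics,
    decision_curve,
    fold_ci,
    pooled_t_from_summary,
)


class TestConfusionMetrics:
    def test_hand_worked_counts(self):
        # TP=3, FP=1, TN=5, FN=1
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = confusion_metrics(y, p)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 5, 1)
        assert m.acc == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(5 / 6)
        assert m.f1 == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        for v in (m.acc, m.recall, m.specificity, m.ppv, m.npv, m.f1):
            assert v == 1.0

    def test_all_positive_predictor_at_one_third_prevalence(self):
        y = [1] * 10 + [0] * 20
        m = confusion_metrics(y, [1] * 30)
        assert m.recall == 1.0
        assert m.specificity == 0.0
        assert m.acc == pytest.approx(1 / 3)
        assert m.f1 == pytest.approx(0.5)
        assert m.npv == 0.0  # degenerate denominator convention

    def test_fuzz_against_brute_force_counting(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            m = confusion_metrics(y, p)
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
            assert m.acc == pytest.approx((tp + tn) / 30)
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no samples"):
            confusion_metrics([], [])


class TestAuc:
    def test_perfect_and_constant(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(20), 1)  # coarse scores force ties
        total, wins = 0, 0.0
        for i in range(20):
            for j in range(20):
                if y[i] == 1 and y[j] == 0:
                    total += 1
                    wins += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert auc(y, s) == pytest.approx(wins / total)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        assert auc(y, s) == pytest.approx(auc(y, np.exp(3 * s) + 1))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="undefined AUC"):
            auc([1, 1], [0.2, 0.4])


class TestFoldStatistics:
    def test_fold_ci_closed_form(self):
        vals = [0.7, 0.72, 0.74, 0.76, 0.78]
        mean, lo, hi = fold_ci(vals)
        sd = np.std(vals, ddof=1)
        half = stats.t.ppf(0.975, 4) * sd / np.sqrt(5)
        assert mean == pytest.approx(0.74)
        assert hi - mean == pytest.approx(half)
        assert lo <= mean <= hi

    def test_identical_fold_values_zero_width(self):
        mean, lo, hi = fold_ci([0.6] * 5)
        assert mean == lo == hi == 0.6

    def test_insufficient_folds(self):
        with pytest.raises(ValueError, match="insufficient folds"):
            fold_ci([0.7])

    def test_cohens_d_cases(self, rng):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
        a = rng.normal(1.0, 1.0, 2000)
        b = rng.normal(0.0, 1.0, 2000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.1)
        x = rng.normal(size=9)
        z = rng.normal(size=7)
        pooled = np.sqrt(((8 * np.var(x, ddof=1)) + (6 * np.var(z, ddof=1))) / 14)
        assert cohens_d(x, z) == pytest.approx((x.mean() - z.mean()) / pooled)

    def test_metric_report_summary(self):
        folds = [confusion_metrics([0, 1], [0, 1]) for _ in range(5)]
        for m, a in zip(folds, [0.7, 0.72, 0.74, 0.76, 0.78]):
            m.auc = a
        rep = MetricReport(folds=folds)
        s = rep.summary()["AUC"]
        assert s["mean"] == pytest.approx(0.74)
        assert s["ci_low"] < 0.74 < s["ci_high"]


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit(self):
        y = [1, 1, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.2, 0.1, 0.15, 0.05]
        # thresholds below the smallest positive score (0.8) yet above every
        # negative score, so there are no false positives
        curve, reports = decision_curve(y, p, np.array([0.3, 0.5, 0.7]))
        assert np.allclose(curve.nb_model, np.mean(y))  # no FP below 0.8
        assert np.all(curve.nb_treat_none == 0)
        assert reports["youden"].youden_j == pytest.approx(1.0)

    def test_hand_worked_net_benefit(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.6, 0.1, 0.7, 0.3, 0.1, 0.1, 0.1, 0.1, 0.1])
        curve, _ = decision_curve(y, p, np.array([0.2]))
        # at t=0.2: TP = 2 (0.9, 0.6), FP = 2 (0.7, 0.3); NB = 0.2 - 0.2*0.25
        assert curve.nb_model[0] == pytest.approx(2 / 10 - (2 / 10) * 0.25)

    def test_net_benefit_bounded_by_prevalence(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        p = rng.random(40)
        curve, _ = decision_curve(y, p, np.linspace(0.05, 0.9, 10))
        assert np.all(curve.nb_model <= y.mean() + 1e-12)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="invalid threshold"):
            decision_curve([0, 1], [0.2, 0.8], np.array([1.5]))


class TestCohortStatistics:
    def test_chi_square_reproduces_imn_comparison(self):
        chi2, df, p = chi_square_2xk([[82, 33], [17, 16]])
        assert df == 1
        assert round(p, 3) == 0.033

    def test_proportional_table_is_null(self):
        chi2, _, p = chi_square_2xk([[20, 10], [40, 20]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_cellwise_oracle_random_2x2(self, rng):
        t = rng.integers(5, 50, size=(2, 2)).astype(float)
        chi2, _, _ = chi_square_2xk(t)
        row, col, n = t.sum(1), t.sum(0), t.sum()
        acc = 0.0
        for i in range(2):
            for j in range(2):
                e = row[i] * col[j] / n
                acc += (t[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(acc)

    def test_chi2_equals_squared_proportion_ztest(self, rng):
        t = rng.integers(10, 60, size=(2, 2)).astype(float)
        chi2, _, _ = chi_square_2xk(t)
        n1, n2 = t[0].sum(), t[1].sum()
        p1, p2 = t[0, 0] / n1, t[1, 0] / n2
        pp = (t[0, 0] + t[1, 0]) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z ** 2)

    def test_degenerate_table(self):
        with pytest.raises(ValueError, match="degenerate table"):
            chi_square_2xk([[0, 0], [3, 4]])

    def test_pooled_t_reproduces_ptv_comparison(self):
        t, df, p = pooled_t_from_summary(SummaryPair(648.0, 374.3, 99),
                                         SummaryPair(814.5, 394.1, 49))
        assert df == 146
        assert round(p, 3) == 0.013

    def test_equal_means(self):
        t, _, p = pooled_t_from_summary(SummaryPair(5, 1, 10), SummaryPair(5, 1, 12))
        assert t == 0.0
        assert p == 1.0

    def test_p_matches_density_quadrature(self, rng):
        a = SummaryPair(float(rng.normal(10, 2)), 2.0, 15)
        b = SummaryPair(float(rng.normal(11, 2)), 2.5, 12)
        t, df, p = pooled_t_from_summary(a, b)
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), abs(t), np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-6)

    def test_table_reports_cover_all_rows(self):
        clin = tables.clinical_comparison_report()
        dvh = tables.dvh_comparison_report()
        assert set(clin) == set(tables.TABLE1_COUNTS)
        assert set(dvh) == set(tables.TABLE2_SUMMARIES)


def test_brier_score_is_mean_squared_error(rng):
    y = rng.integers(0, 2, 25)
    p = rng.random(25)
    assert brier_score(y, p) == pytest.approx(np.mean((p - y) ** 2))
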