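"""ROC/AUC, bootstrap, paired comparison, confusion, calibration, DCA, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnrad.evaluation import (
    bootstrap_auc_ci,
    calibration_curve,
    compare_auc_paired,
    confusion_metrics,
    decision_curve,
    reconstruct_confusion,
    roc_auc,
    spearman_to_volume,
    univariate_screen,
)

import oracles


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_worked_example_three_of_four_pairs(self):
        auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            s = rng.normal(0, 1, 30)
            y = (rng.random(30) < 0.5).astype(int)
            if y.sum() in (0, 30):
                continue
            s[rng.random(30) < 0.3] = 0.0  # inject ties
            assert roc_auc(s, y) == pytest.approx(oracles.auc_pair_counting(s, y))

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(0, 1, 40)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        a = roc_auc(s, y)
        assert roc_auc(np.exp(2 * s) + 7, y) == pytest.approx(a)
        assert roc_auc(np.arctan(s), y) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestBootstrapCI:
    def test_seed_determinism(self, rng):
        s = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.6).astype(int)
        a = bootstrap_auc_ci(s, y, n_boot=200, seed=3)
        b = bootstrap_auc_ci(s, y, n_boot=200, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_perfect_separation_degenerate_interval(self):
        s = np.r_[np.zeros(20), np.ones(20)]
        y = s.astype(int)
        res = bootstrap_auc_ci(s, y, n_boot=100, seed=0)
        assert res.auc == 1.0 and res.ci_low == 1.0 and res.ci_high == 1.0

    def test_interval_contains_estimate_and_covers_truth(self):
        """~95% outer coverage of a known AUC 0.8 (binormal model)."""
        # AUC = Phi(mu/sqrt(2)) = 0.8  ->  mu = sqrt(2) * Phi^-1(0.8)
        import scipy.stats as stx

        mu = np.sqrt(2) * stx.norm.ppf(0.8)
        cover = 0
        reps = 40
        for k in range(reps):
            rng = np.random.default_rng(k)
            y = np.r_[np.zeros(250), np.ones(250)].astype(int)
            s = np.r_[rng.normal(0, 1, 250), rng.normal(mu, 1, 250)]
            res = bootstrap_auc_ci(s, y, n_boot=200, seed=k)
            assert res.ci_low <= res.auc <= res.ci_high
            cover += res.ci_low <= 0.8 <= res.ci_high
        assert cover / reps >= 0.85  # binomial slack around the nominal 95%


class TestPairedComparison:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.normal(0, 1, 40)
        y = (rng.random(40) < 0.5).astype(int)
        assert compare_auc_paired(s, s, y) == 1.0

    def test_symmetry_in_model_order(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        y = (rng.random(50) < 0.5).astype(int)
        p1 = compare_auc_paired(a, b, y, seed=5)
        p2 = compare_auc_paired(b, a, y, seed=5)
        assert p1 == pytest.approx(p2)

    def test_perfect_vs_random_significant(self, rng):
        y = (rng.random(100) < 0.5).astype(int)
        perfect = y + 0.01 * rng.random(100)
        random_scores = rng.normal(0, 1, 100)
        assert compare_auc_paired(perfect, random_scores, y, seed=2) < 0.01


class TestConfusion:
    @pytest.mark.parametrize(
        "tp,fp,fn,tn,mcc,bal,ppv,npv",
        [
            (49, 7, 0, 6, 0.64, 0.73, 0.88, 1.00),   # combined-model row
            (48, 4, 1, 9, 0.74, 0.84, 0.92, 0.90),   # LBP-model row
            (17, 0, 32, 13, 0.32, 0.67, 1.00, 0.29), # short-diameter row
        ],
    )
    def test_clinical_rows_reproduce_printed_metrics(self, tp, fp, fn, tn, mcc, bal, ppv, npv):
        pred = np.r_[np.ones(tp + fp), np.zeros(fn + tn)]
        y = np.r_[np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
        m = confusion_metrics(pred, y)
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
        assert round(m.mcc, 2) == mcc
        assert round(m.balanced_accuracy, 2) == bal
        assert round(m.ppv, 2) == ppv
        assert round(m.npv, 2) == npv

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        m = confusion_metrics(y, y)
        assert m.mcc == 1.0 and m.sensitivity == 1.0 and m.specificity == 1.0

    def test_degenerate_all_positive_prediction_flagged(self):
        m = confusion_metrics(np.ones(10), np.ones(10))
        assert m.degenerate and m.mcc == 0.0

    def test_reconstruction_from_printed_rates(self):
        m = reconstruct_confusion(0.35, 1.00, 49, 13)
        assert (m.tp, m.fn, m.fp, m.tn) == (17, 32, 0, 13)
        m = reconstruct_confusion(0.98, 0.69, 49, 13)
        assert (m.tp, m.tn) == (48, 9)
        m = reconstruct_confusion(1.0, 1.0, 7, 5)
        assert (m.tp, m.fp, m.fn, m.tn) == (7, 0, 0, 5)


class TestCalibration:
    def test_calibrated_by_construction(self, rng):
        p = rng.random(2000)
        y = (rng.random(2000) < p).astype(int)
        table = calibration_curve(p, y)
        assert (abs(table.mean_predicted - table.observed_fraction) < 0.1).all()

    def test_degenerate_zero_probabilities(self):
        table = calibration_curve(np.zeros(5), np.zeros(5))
        assert len(table) == 1
        assert table.iloc[0].mean_predicted == 0.0
        assert table.iloc[0].observed_fraction == 0.0

    def test_constant_half_probability_shows_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        table = calibration_curve(np.full(100, 0.5), y)
        assert len(table) == 1
        assert table.iloc[0].observed_fraction == pytest.approx(0.3)


class TestDecisionCurve:
    def test_treat_all_closed_form(self, rng):
        p = rng.random(200)
        y = (rng.random(200) < 0.7).astype(int)
        pi = y.mean()
        dc = decision_curve(p, y, thresholds=[0.0, 0.25, 0.5, 0.75]).table
        for _, row in dc.iterrows():
            w = row.threshold / (1 - row.threshold)
            assert row.nb_all == pytest.approx(pi - (1 - pi) * w)
            assert row.nb_none == 0.0

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.r_[np.ones(70), np.zeros(30)].astype(int)
        p = y.astype(float)
        dc = decision_curve(p, y, thresholds=[0.1, 0.5, 0.9]).table
        assert np.allclose(dc.nb_model, 0.7)

    def test_short_diameter_row_net_benefit(self):
        # TP=17, FP=0 among n=62 at p_t = 0.5: NB = 17/62
        y = np.r_[np.ones(17), np.ones(32), np.zeros(13)].astype(int)
        p = np.r_[np.ones(17), np.zeros(32), np.zeros(13)]
        dc = decision_curve(p, y, thresholds=[0.5]).table
        assert dc.iloc[0].nb_model == pytest.approx(17 / 62)

    def test_model_never_beats_perfect(self, rng):
        p = rng.random(300)
        y = (rng.random(300) < 0.6).astype(int)
        dc = decision_curve(p, y).table
        assert (dc.nb_model <= y.mean() + 1e-12).all()

    def test_threshold_one_rejected(self, rng):
        with pytest.raises(ValueError):
            decision_curve(rng.random(10), np.ones(10), thresholds=[1.0])


class TestUnivariateScreen:
    def test_null_rejection_rate_near_alpha(self, rng):
        n, m = 200, 80
        X = pd.DataFrame(rng.normal(0, 1, (n, m)), columns=[f"f{i}" for i in range(m)])
        y = (rng.random(n) < 0.5).astype(int)
        table = univariate_screen(X, y)
        raw_rate = (table.p_value < 0.05).mean()
        assert abs(raw_rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_bonferroni_caps_at_one(self, rng):
        X = pd.DataFrame({"f": rng.normal(0, 1, 100)})
        y = (rng.random(100) < 0.5).astype(int)
        table = univariate_screen(pd.concat([X] * 156, axis=1, keys=range(156)), y)
        assert (table.p_adjusted <= 1.0).all()

    def test_small_sample_matches_exact_enumeration(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        X = pd.DataFrame({"f": np.r_[a, b]})
        y = np.r_[np.ones(3), np.zeros(3)].astype(int)
        table = univariate_screen(X, y)
        assert table.iloc[0].p_value == pytest.approx(oracles.wilcoxon_exact_p(a, b))

    def test_constant_feature_flagged(self, rng):
        X = pd.DataFrame({"c": np.ones(40), "x": rng.normal(0, 1, 40)})
        y = (rng.random(40) < 0.5).astype(int)
        table = univariate_screen(X, y).set_index("feature")
        assert table.loc["c"].degenerate and table.loc["c"].p_value == 1.0


class TestSpearman:
    def test_perfect_and_inverse_correlation(self, rng):
        v = rng.random(30) * 100
        X = pd.DataFrame({"same": v, "neg": -v})
        table = spearman_to_volume(X, v).set_index("feature")
        assert table.loc["same"].rho == pytest.approx(1.0)
        assert table.loc["neg"].rho == pytest.approx(-1.0)
        assert table.loc["same"].correlated and table.loc["neg"].correlated

    def test_midrank_ties_hand_computed(self):
        # x = [1, 2, 2, 3], v = [10, 20, 30, 40]
        # ranks x: [1, 2.5, 2.5, 4], ranks v: [1, 2, 3, 4] -> rho = 0.9487
        X = pd.DataFrame({"x": [1.0, 2.0, 2.0, 3.0]})
        v = [10.0, 20.0, 30.0, 40.0]
        rho = spearman_to_volume(X, v).iloc[0].rho
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        rv = np.array([1.0, 2.0, 3.0, 4.0])
        expected = np.corrcoef(rx, rv)[0, 1]
        assert rho == pytest.approx(expected)
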