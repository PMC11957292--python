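"""Correlation, Welch tests, LDA/QDA decision rule, CV and pair ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phasetrack.discrimination import (
    DiscriminantAnalysis,
    classify,
    confusion_metrics,
    correlation_matrix,
    fit_lda,
    fit_qda,
    kfold_cv,
    pair_search,
    pearson_corr,
    welch_t_test,
)
from phasetrack.motility import PARAMETER_NAMES
from phasetrack.synthetic import simulate_feature_table

from _reference import mahalanobis_sq_loop, welch_textbook


def _two_gaussians(rng, n=40, shift=4.0, dim=2):
    X1 = rng.normal(0, 1, (n, dim)) + shift
    X2 = rng.normal(0, 1, (n, dim))
    return X1, X2


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_matches_definition(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        sxy = np.cov(x, y, ddof=1)[0, 1]
        assert pearson_corr(x, y) == pytest.approx(
            sxy / (x.std(ddof=1) * y.std(ddof=1)), abs=1e-12
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        tab = pd.DataFrame(rng.normal(size=(30, 10)), columns=PARAMETER_NAMES)
        corr = correlation_matrix(tab)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_column_flagged_nan(self, rng):
        tab = pd.DataFrame(rng.normal(size=(20, 10)), columns=PARAMETER_NAMES)
        tab["quiescent_time_s"] = 5.0
        corr = correlation_matrix(tab)
        assert corr["quiescent_time_s"].isna().all()

    def test_informative_pair_negatively_correlated_in_cancer_like_table(self):
        tab = simulate_feature_table(n_per_class=60, effect=2.0, seed=11)
        # within the pooled table the two shifted columns co-vary positively
        pos = tab[tab.label == 1]
        r = pearson_corr(
            tab["freq_turns_below_30"], tab["sum_turn_angles_deg"]
        )
        assert r > 0.3  # shared class shift induces correlation


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_p_monotone_in_shift(self):
        a = np.array([1.0, 2.0, 3.0])
        ps = [welch_t_test(a, a + d)[2] for d in (1.0, 2.0, 4.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_matches_textbook_formula(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 20)
        got = welch_t_test(a, b)
        exp = welch_textbook(a, b)
        assert got == pytest.approx(exp, abs=1e-10)


class TestFitting:
    def test_pooled_covariance_arithmetic(self, rng):
        # equal n, S1 = 2I, S2 = 4I -> pooled 3I (within sampling identity)
        X1, X2 = _two_gaussians(rng, n=30)
        m = fit_lda(X1, X2)
        S1 = np.cov(X1, rowvar=False, ddof=1)
        S2 = np.cov(X2, rowvar=False, ddof=1)
        exp = (29 * S1 + 29 * S2) / 58
        assert np.allclose(m.pooled_cov, exp, atol=1e-12)

    def test_lda_matches_sklearn_decisions(self, rng):
        """Independent cross-check: equal-prior sklearn LDA predicts identically."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X1, X2 = _two_gaussians(rng, n=50, shift=1.5)
        m = fit_lda(X1, X2)
        grid = rng.normal(0.75, 2.0, (300, 2))
        ours = classify(m, grid)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        sk.fit(np.vstack([X1, X2]), np.r_[np.ones(50), 2 * np.ones(50)])
        assert np.array_equal(ours, sk.predict(grid).astype(int))

    def test_qda_mahalanobis_matches_loop_oracle(self, rng):
        X1, X2 = _two_gaussians(rng, n=25, shift=2.0, dim=3)
        m = fit_qda(X1, X2)
        for _ in range(20):
            x = rng.normal(1, 2, 3)
            d1, d2 = m.mahalanobis_sq(x)
            assert d1[0] == pytest.approx(
                mahalanobis_sq_loop(x, m.mean1, m.cov1), abs=1e-9
            )
            assert d2[0] == pytest.approx(
                mahalanobis_sq_loop(x, m.mean2, m.cov2), abs=1e-9
            )

    def test_singular_covariance_rejected(self):
        X1 = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])  # rank 1
        X2 = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError, match="parameter pair"):
            fit_qda(X1, X2)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            fit_lda(rng.normal(size=(2, 2)), rng.normal(size=(10, 2)))


class TestDecisionRule:
    def test_class_means_classified_to_own_class(self, rng):
        X1, X2 = _two_gaussians(rng)
        for kind, fitter in (("lda", fit_lda), ("qda", fit_qda)):
            m = fitter(X1, X2)
            assert classify(m, m.mean1)[0] == 1
            assert classify(m, m.mean2)[0] == 2

    def test_lda_equals_qda_when_covariances_equal(self, rng):
        """With S1 = S2 exactly, both rules compare the same distances."""
        base = rng.normal(size=(30, 2))
        X1 = base + [3.0, 0.0]
        X2 = base.copy()  # identical sample covariance by construction
        lda, qda = fit_lda(X1, X2), fit_qda(X1, X2)
        grid = rng.normal(1.5, 3.0, (400, 2))
        assert np.array_equal(classify(lda, grid), classify(qda, grid))

    def test_1d_equal_variance_boundary_at_midpoint(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, (200, 1))
        X1, X2 = base + 4.0, base.copy()
        m = fit_lda(X1, X2)
        mid = (m.mean1[0] + m.mean2[0]) / 2
        eps = 1e-9
        assert classify(m, [[mid + eps]])[0] == 1
        assert classify(m, [[mid - eps]])[0] == 2
        assert classify(m, [[mid]])[0] == 1  # exact tie -> positive

    def test_decision_matches_distance_sign_oracle(self, rng):
        X1, X2 = _two_gaussians(rng, n=30, shift=2.0)
        m = fit_qda(X1, X2)
        grid = np.array(
            list(itertools.product(np.linspace(-3, 6, 20), repeat=2))
        )
        labels = classify(m, grid)
        for x, lab in zip(grid, labels):
            d1 = mahalanobis_sq_loop(x, m.mean1, m.cov1)
            d2 = mahalanobis_sq_loop(x, m.mean2, m.cov2)
            assert lab == (1 if d1 <= d2 else 2)

    def test_affine_invariance_of_classification(self, rng):
        """Mahalanobis rule is invariant to a common affine feature rescaling."""
        X1, X2 = _two_gaussians(rng, n=40, shift=1.0)
        A = np.array([[2.0, 0.3], [-0.5, 4.0]])
        b = np.array([7.0, -2.0])
        grid = rng.normal(0.5, 2.0, (200, 2))
        for fitter in (fit_lda, fit_qda):
            m0 = fitter(X1, X2)
            m1 = fitter(X1 @ A.T + b, X2 @ A.T + b)
            assert np.array_equal(classify(m0, grid), classify(m1, grid @ A.T + b))


class TestConfusionMetrics:
    def test_all_correct_and_all_wrong(self):
        ones = np.ones(10, dtype=int)
        twos = 2 * np.ones(10, dtype=int)
        perfect = confusion_metrics(np.r_[ones, twos], np.r_[ones, twos])
        assert (perfect.sensitivity, perfect.specificity, perfect.accuracy) == (1, 1, 1)
        wrong = confusion_metrics(np.r_[twos, ones], np.r_[ones, twos])
        assert (wrong.sensitivity, wrong.specificity, wrong.accuracy) == (0, 0, 0)

    def test_constructed_50_50_matrix(self):
        # tp=47 fn=3 tn=37 fp=13 -> sens 94.0%, spec 74.0%, acc 84.0%
        actual = np.r_[np.ones(50, int), 2 * np.ones(50, int)]
        predicted = np.r_[
            np.ones(47, int), 2 * np.ones(3, int), np.ones(13, int), 2 * np.ones(37, int)
        ]
        m = confusion_metrics(predicted, actual)
        assert (m.tp, m.fn, m.fp, m.tn) == (47, 3, 13, 37)
        assert m.sensitivity == pytest.approx(0.94)
        assert m.specificity == pytest.approx(0.74)
        assert m.accuracy == pytest.approx(0.84)

    def test_formulas_by_exhaustive_enumeration(self):
        """Rates match their defining ratios for every matrix with counts <= 5."""
        for tp in range(6):
            for fp in range(6):
                for fn in range(6):
                    for tn in range(6):
                        if tp + fn == 0 or tn + fp == 0:
                            continue
                        actual = [1] * (tp + fn) + [2] * (tn + fp)
                        predicted = (
                            [1] * tp + [2] * fn + [1] * fp + [2] * tn
                        )
                        m = confusion_metrics(predicted, actual)
                        assert m.sensitivity == tp / (tp + fn)
                        assert m.specificity == tn / (tn + fp)
                        assert m.accuracy == (tp + tn) / (tp + fp + fn + tn)


class TestCrossValidation:
    def test_perfectly_separated_classes_100_percent(self, rng):
        tab = simulate_feature_table(n_per_class=30, effect=12.0, seed=1)
        m = kfold_cv(tab, ["freq_turns_below_30", "sum_turn_angles_deg"], "lda")
        assert m.accuracy == 1.0

    def test_null_labels_near_chance(self):
        tab = simulate_feature_table(n_per_class=60, effect=0.0, seed=2)
        m = kfold_cv(tab, ["mean_speed_um_s", "quiescent_time_s"], "qda", seed=3)
        assert 0.3 <= m.accuracy <= 0.7

    def test_same_seed_identical_metrics(self):
        tab = simulate_feature_table(n_per_class=25, effect=1.0, seed=4)
        cols = ["freq_turns_below_30", "sum_turn_angles_deg"]
        assert kfold_cv(tab, cols, "qda", seed=9) == kfold_cv(tab, cols, "qda", seed=9)

    def test_class_smaller_than_k_rejected(self):
        tab = simulate_feature_table(n_per_class=5, seed=0)
        with pytest.raises(ValueError, match="k="):
            kfold_cv(tab, ["mean_speed_um_s", "quiescent_time_s"], "lda", k=10)

    def test_missing_rows_dropped_before_fit(self):
        tab = simulate_feature_table(n_per_class=30, effect=8.0, seed=6)
        tab.loc[3, "md_between_turns_30"] = np.nan
        m = kfold_cv(tab, ["md_between_turns_30", "sum_turn_angles_deg"], "lda")
        assert m.tp + m.fp + m.fn + m.tn == len(tab) - 1


class TestPairSearch:
    def test_informative_pair_ranks_first(self):
        tab = simulate_feature_table(
            n_per_class=50,
            informative_pair=("freq_turns_below_30", "sum_turn_angles_deg"),
            effect=2.5,
            seed=10,
        )
        ranking = pair_search(tab, kinds=("qda",), seed=0)
        assert ranking.iloc[0]["parameters"] == "freq_turns_below_30 + sum_turn_angles_deg"

    def test_row_count_is_45_per_kind(self, rng):
        tab = simulate_feature_table(n_per_class=20, effect=1.0, seed=12)
        ranking = pair_search(tab, kinds=("lda", "qda"), seed=0)
        assert len(ranking) == 90

    def test_pure_noise_top_accuracy_near_chance(self):
        tab = simulate_feature_table(n_per_class=40, effect=0.0, seed=13)
        ranking = pair_search(tab, kinds=("lda",), seed=0)
        # best of 45 null pairs: above 0.5 by selection, but far from separable
        assert ranking.iloc[0]["accuracy"] <= 0.75
        assert ranking["accuracy"].median() == pytest.approx(0.5, abs=0.12)


class TestModelFacade:
    def test_fit_summary_and_boundary(self):
        tab = simulate_feature_table(n_per_class=40, effect=3.0, seed=20)
        res = DiscriminantAnalysis(
            tab, ["freq_turns_below_30", "sum_turn_angles_deg"], kind="qda"
        ).fit()
        s = res.summary()
        assert "QDA" in s and "10-fold CV" in s
        assert res.cv.accuracy > 0.9
        poly = res.decision_boundary((-4, 7))
        assert poly.ndim == 2 and poly.shape[1] == 2 and len(poly) > 5
        # boundary points are near-equidistant in Mahalanobis terms
        vals = res.model.decision_values(poly)
        assert np.quantile(np.abs(vals), 0.9) < 0.5

    def test_resubstitution_at_least_chance_on_separable_data(self):
        tab = simulate_feature_table(n_per_class=30, effect=2.0, seed=21)
        res = DiscriminantAnalysis(
            tab, ["freq_turns_below_30", "sum_turn_angles_deg"], kind="lda"
        ).fit()
        assert res.resubstitution.accuracy >= 0.5
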