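import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from texturestager.modeling import (
    _fit_logit,
    forward_stepwise_logistic,
    hosmer_lemeshow,
    roc_analysis,
    run_model_suite,
)
from texturestager.stats import UnivariateResult

from oracles import auc_pair_fraction


def _uni(name, significant=True):
    return UnivariateResult(
        feature_name=name, test_used="t-test", p_value=0.01 if significant else 0.5,
        group_summaries={}, significant=significant, alpha=0.05,
    )


class TestLogisticFit:
    def test_newton_fixed_point_on_six_points(self):
        """MLE agrees with an independently coded Newton iteration."""
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        X = np.column_stack([np.ones(6), x])
        beta = np.zeros(2)
        for _ in range(200):
            p = 1 / (1 + np.exp(-X @ beta))
            grad = X.T @ (y - p)
            hess = -(X * (p * (1 - p))[:, None]).T @ X
            beta = beta - np.linalg.solve(hess, grad)
            if np.linalg.norm(grad) < 1e-10:
                break
        res = _fit_logit(x[:, None], y)
        np.testing.assert_allclose(res.params, beta, atol=1e-6)

    def test_binary_predictor_coefficient_equals_log_odds_ratio(self):
        # 2x2 table: exposed 30 (18 events), unexposed 30 (6 events)
        x = np.array([1] * 30 + [0] * 30, dtype=float)
        y = np.array([1] * 18 + [0] * 12 + [1] * 6 + [0] * 24)
        res = _fit_logit(x[:, None], y)
        log_or = np.log((18 / 12) / (6 / 24))
        assert res.params[1] == pytest.approx(log_or, abs=1e-6)


class TestForwardStepwise:
    def test_single_candidate_reduces_to_lr_test(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        x = y + rng.normal(0, 1.0, 80)
        feats = pd.DataFrame({"f": x})
        model = forward_stepwise_logistic(feats, y)
        # oracle: explicit LR test of f vs intercept-only
        llf1 = _fit_logit(x[:, None], y).llf
        llf0 = _fit_logit(np.empty((80, 0)), y).llf
        p = sps.chi2.sf(2 * (llf1 - llf0), 1)
        assert model.selected_features == (["f"] if p < 0.05 else [])

    def test_informative_feature_selected_noise_rejected(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 100 + [1] * 100)
        feats = pd.DataFrame(
            {"signal": y + rng.normal(0, 0.5, 200), "noise": rng.normal(0, 1, 200)}
        )
        model = forward_stepwise_logistic(feats, y)
        assert model.selected_features == ["signal"]

    def test_pure_noise_rarely_enters(self):
        rng = np.random.default_rng(2)
        entries = 0
        reps = 100
        y = np.array([0] * 50 + [1] * 50)
        for _ in range(reps):
            feats = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
            entries += len(forward_stepwise_logistic(feats, y).selected_features)
        # per-candidate false-entry rate ~5% -> ~10 entries over 100 reps x 2
        assert entries <= 25

    def test_odds_ratio_consistent_with_coefficients(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 60 + [1] * 60)
        feats = pd.DataFrame({"f": y + rng.normal(0, 0.8, 120)})
        m = forward_stepwise_logistic(feats, y)
        assert m.selected_features == ["f"]
        b, se = m.coefficients["f"], m.std_errors["f"]
        assert m.odds_ratios["f"] == pytest.approx(np.exp(b))
        assert m.ci_low["f"] == pytest.approx(np.exp(b - 1.959963984540054 * se))
        assert m.ci_high["f"] == pytest.approx(np.exp(b + 1.959963984540054 * se))
        assert 0 < m.hl_p <= 1

    def test_perfectly_separating_feature_flagged(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 30 + [1] * 30)
        feats = pd.DataFrame(
            {"sep": y.astype(float), "ok": y + rng.normal(0, 1.0, 60)}
        )
        m = forward_stepwise_logistic(feats, y)
        assert "sep" in m.separation_flags
        assert "sep" not in m.selected_features

    def test_missing_values_rejected(self):
        y = np.array([0] * 20 + [1] * 20)
        feats = pd.DataFrame({"f": [np.nan] + [0.0] * 39})
        with pytest.raises(ValueError, match="missing"):
            forward_stepwise_logistic(feats, y)


class TestHosmerLemeshow:
    def test_statistic_matches_hand_tabulated_20_subjects(self):
        # 10 pairs of subjects with distinct probabilities
        p = np.repeat(np.linspace(0.05, 0.95, 10), 2)
        y = np.array([0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1, 1, 1])
        stat = 0.0
        for g in range(10):
            pp, yy = p[2 * g : 2 * g + 2], y[2 * g : 2 * g + 2]
            e1, o1 = pp.sum(), yy.sum()
            e0, o0 = 2 - e1, 2 - o1
            stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        res = hosmer_lemeshow(p, y, n_groups=10)
        assert res.statistic == pytest.approx(stat)
        assert res.df == 8
        assert res.p_value == pytest.approx(sps.chi2.sf(stat, 8))

    def test_constant_half_probabilities_give_p_one(self):
        p = np.full(40, 0.5)
        y = np.array([0, 1] * 20)
        res = hosmer_lemeshow(p, y)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_zero_expected_group_merged_with_warning(self):
        p = np.concatenate([np.zeros(4), np.linspace(0.2, 0.9, 36)])
        y = (np.random.default_rng(0).random(40) < p).astype(int)
        with pytest.warns(UserWarning, match="merged"):
            res = hosmer_lemeshow(p, y, n_groups=10)
        assert res.merged

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            hosmer_lemeshow(np.full(10, 0.5), np.zeros(10), n_groups=10)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.3], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.sensitivity == 100.0
        assert roc.specificity == 100.0
        assert roc.direction == ">"

    def test_auc_equals_pair_fraction_on_small_inputs(self, rng):
        for _ in range(50):
            n = rng.integers(4, 13)
            labels = np.zeros(n, int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            if np.unique(scores).size == 1:
                continue
            roc = roc_analysis(scores, labels)
            frac = auc_pair_fraction(scores, labels)
            assert roc.auc == pytest.approx(max(frac, 1 - frac))

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        scores[labels == 1] += 0.8
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=500)
        labels = rng.permutation([0] * 250 + [1] * 250)
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_youden_cutoff_maximizes_j_over_thresholds(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        scores[labels == 1] += 1.0
        roc = roc_analysis(scores, labels)
        assert roc.direction == ">"
        best_j = max(
            np.mean(scores[labels == 1] > c) + np.mean(scores[labels == 0] <= c) - 1
            for c in scores
        )
        assert roc.youden == pytest.approx(best_j)
        sens = 100 * np.mean(scores[labels == 1] > roc.cutoff)
        spec = 100 * np.mean(scores[labels == 0] <= roc.cutoff)
        assert roc.sensitivity == pytest.approx(sens)
        assert roc.specificity == pytest.approx(spec)

    def test_reversed_marker_reported_with_less_than_direction(self):
        # low scores indicate the positive class
        roc = roc_analysis([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert roc.direction == "<"
        assert roc.auc == 1.0
        assert roc.cutoff_label.startswith("<")

    def test_constant_scores_flagged(self):
        roc = roc_analysis([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert roc.degenerate
        assert roc.auc == 0.5
        assert roc.cutoff is None

    def test_delong_ci_contains_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(11)

        def width(n):
            scores = rng.normal(size=n)
            labels = np.array([0] * (n // 2) + [1] * (n // 2))
            scores[labels == 1] += 1.0
            r = roc_analysis(scores, labels)
            assert r.ci_low <= r.auc <= r.ci_high
            return r.ci_high - r.ci_low

        assert width(400) < width(40)


class TestRunModelSuite:
    def _cohort_features(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = np.array([0] * n + [1] * n)
        return (
            pd.DataFrame(
                {
                    "sagittal_ENE": rng.normal(0, 1, 2 * n),
                    "axial_ENE": y + rng.normal(0, 0.5, 2 * n),
                    "axial_ENT": y + rng.normal(0, 0.7, 2 * n),
                }
            ),
            y,
        )

    def test_combined_candidates_are_union_of_scope_lists(self):
        feats, y = self._cohort_features()
        uni = [_uni("sagittal_ENE"), _uni("axial_ENE"), _uni("axial_ENT")]
        suite = run_model_suite(feats, y, uni)
        assert set(suite["combined"].candidates) == set(
            suite["sagittal"].candidates
        ) | set(suite["axial"].candidates)

    def test_signal_only_in_axial_features(self):
        feats, y = self._cohort_features(seed=1)
        uni = [_uni("sagittal_ENE"), _uni("axial_ENE"), _uni("axial_ENT")]
        suite = run_model_suite(feats, y, uni)
        assert "axial_ENE" in suite["axial"].model.selected_features
        assert suite["sagittal"].model.selected_features == []

    def test_scope_without_candidates_skipped_with_warning(self):
        feats, y = self._cohort_features(seed=2)
        uni = [_uni("axial_ENE")]
        with pytest.warns(UserWarning, match="sagittal"):
            suite = run_model_suite(feats, y, uni)
        assert suite["sagittal"].skipped

    def test_reports_carry_or_ci_p_fields(self):
        feats, y = self._cohort_features(seed=3)
        uni = [_uni("sagittal_ENE"), _uni("axial_ENE"), _uni("axial_ENT")]
        suite = run_model_suite(feats, y, uni)
        for scope in ("axial", "combined"):
            m = suite[scope].model
            for f in m.selected_features:
                assert f in m.odds_ratios
                assert m.ci_low[f] < m.odds_ratios[f] < m.ci_high[f]
                assert 0 <= m.p_values[f] <= 1
            assert suite[scope].roc is not None
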