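"""ROC/AUC, Youden threshold selection, and the logistic marker panel."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

import uroscreen as u
from uroscreen.datamodel import CASE, CONTROL

from conftest import make_pm


def concordance_auc(case_scores, control_scores):
    """Mann-Whitney concordance probability, ties counted one half."""
    case_scores = np.asarray(case_scores)[:, None]
    control_scores = np.asarray(control_scores)[None, :]
    wins = (case_scores > control_scores).sum()
    ties = (case_scores == control_scores).sum()
    return (wins + 0.5 * ties) / case_scores.size / control_scores.size


def labels(n_case, n_control):
    return [CASE] * n_case + [CONTROL] * n_control


class TestRocCurve:
    def test_small_example_three_of_four_concordant(self):
        roc = u.roc_curve([3, 5, 1, 4], labels(2, 2))
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        roc = u.roc_curve([10, 11, 1, 2], labels(2, 2))
        assert roc.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            u.roc_curve([1, 2], [CASE, CASE])

    def test_auc_equals_concordance_probability(self):
        """AUC-Mann-Whitney identity on random tied instances, to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 15, 2)
            scores = rng.integers(0, 8, n1 + n2).astype(float)  # many ties
            roc = u.roc_curve(scores, labels(n1, n2))
            assert roc.auc == pytest.approx(
                concordance_auc(scores[:n1], scores[n1:]), abs=1e-12
            )

    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=20))
    def test_auc_invariant_under_increasing_transform(self, raw):
        n1 = len(raw) // 2
        scores = np.asarray(raw, dtype=float)
        lab = labels(n1, len(raw) - n1)
        a = u.roc_curve(scores, lab).auc
        b = u.roc_curve(scores**3, lab).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        roc = u.roc_curve(scores, labels(1000, 1000))
        se = np.sqrt((2000 + 1) / (12 * 1000 * 1000))
        assert abs(roc.auc - 0.5) < 3 * se


class TestSelectThreshold:
    def test_specificity_tiebreak_and_midpoint(self):
        roc = u.roc_curve([3, 5, 1, 4], labels(2, 2))
        choice = u.select_threshold(roc)
        assert choice.threshold == pytest.approx(4.5)
        assert (choice.sensitivity, choice.specificity) == (0.5, 1.0)
        assert not choice.degenerate

    def test_perfect_separation_threshold_between_groups(self):
        roc = u.roc_curve([10, 11, 12, 1, 2, 3], labels(3, 3))
        choice = u.select_threshold(roc)
        assert choice.j == pytest.approx(1.0)
        assert 3 < choice.threshold < 10

    def test_identical_scores_flagged_degenerate(self):
        roc = u.roc_curve([7.0] * 6, labels(3, 3))
        choice = u.select_threshold(roc)
        assert choice.j == 0.0 and choice.degenerate

    def test_matches_brute_force_j_maximisation(self):
        """Best J equals an exhaustive scan over all midpoint cutoffs."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n1, n2 = rng.integers(2, 10, 2)
            scores = np.round(rng.normal(size=n1 + n2), 1)
            truth = np.array([True] * n1 + [False] * n2)
            choice = u.select_threshold(u.roc_curve(scores, labels(n1, n2)))
            best = 0.0
            distinct = np.unique(scores)
            cuts = np.concatenate(
                [[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2,
                 [distinct[-1] + 1]]
            )
            for t in cuts:
                pred = scores >= t
                sens = (pred & truth).sum() / truth.sum()
                spec = (~pred & ~truth).sum() / (~truth).sum()
                best = max(best, sens + spec - 1)
            assert choice.j == pytest.approx(best, abs=1e-12)


class TestThresholdClassifier:
    @pytest.fixture()
    def pm(self):
        return make_pm([[5.0, 9.0, 1.0, 3.0]], labels(2, 2))

    def test_threshold_below_all(self, pm):
        acc, sens, spec = u.apply_threshold_classifier(pm, "C0", 0.0)
        assert (sens, spec) == (1.0, 0.0) and acc == 0.5

    def test_threshold_above_all(self, pm):
        acc, sens, spec = u.apply_threshold_classifier(pm, "C0", 1e9)
        assert (sens, spec) == (0.0, 1.0)

    def test_separating_threshold(self, pm):
        acc, sens, spec = u.apply_threshold_classifier(pm, "C0", 4.0)
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_nonfinite_threshold_rejected(self, pm):
        with pytest.raises(ValueError):
            u.apply_threshold_classifier(pm, "C0", np.inf)


class TestLogisticPanel:
    def test_perfect_marker_gives_training_auc_one(self):
        pm = make_pm(
            [[100.0, 120.0, 130.0, 1.0, 2.0, 3.0]], labels(3, 3)
        )
        model = u.fit_logistic_panel(pm, ["C0"])
        assert model.training_roc.auc == 1.0

    def test_upregulated_marker_recovers_positive_coefficient(self):
        pm, planted = u.generate_profile(
            u.SyntheticConfig(n_case=40, n_control=40, m_compounds=20,
                              n_markers=1, n_contaminants=0, seed=6)
        )
        (cid,) = planted
        model = u.fit_logistic_panel(pm, [cid])
        assert model.coefficients[0] > 0

    def test_tiny_ridge_matches_unpenalised_mle(self):
        """With ridge -> 0 on non-separable data the fit converges to the
        maximum-likelihood solution (oracle: statsmodels Logit)."""
        rng = np.random.default_rng(3)
        n, k = 200, 3
        X = rng.lognormal(8, 1, (k, n))
        beta = np.array([2e-4, -1e-4, 5e-5])
        y = rng.random(n) < 1 / (1 + np.exp(-(-1.0 + X.T @ beta)))
        pm = make_pm(X, [CASE if v else CONTROL for v in y])
        model = u.fit_logistic_panel(pm, pm.compound_ids, ridge=1e-10)

        mu, sd = X.T.mean(0), X.T.std(0)
        ref = sm.Logit(
            y.astype(float), sm.add_constant((X.T - mu) / sd)
        ).fit(disp=0, method="newton")
        ref_coef = ref.params[1:] / sd
        ref_b0 = ref.params[0] - np.sum(ref.params[1:] * mu / sd)
        assert model.intercept == pytest.approx(ref_b0, rel=1e-4)
        assert np.allclose(model.coefficients, ref_coef, rtol=1e-4)

    def test_noise_panel_has_bounded_optimism(self):
        """Eight noise features: mean training AUC stays below 0.6."""
        rng = np.random.default_rng(4)
        aucs = []
        for seed in range(25):
            X = rng.lognormal(8, 1, (8, 300))
            groups = rng.permutation(labels(150, 150))
            pm = make_pm(X, groups)
            aucs.append(u.fit_logistic_panel(pm, pm.compound_ids).training_roc.auc)
        assert 0.5 < np.mean(aucs) < 0.6

    def test_empty_marker_list_rejected(self):
        pm = make_pm([[1.0, 2.0]], labels(1, 1))
        with pytest.raises(ValueError):
            u.fit_logistic_panel(pm, [])


class TestEvaluatePanel:
    def test_evaluating_on_training_cohort_reproduces_training_roc(self):
        pm, planted = u.generate_profile(
            u.SyntheticConfig(n_case=20, n_control=20, m_compounds=30,
                              n_markers=2, n_contaminants=0, seed=7)
        )
        model = u.fit_logistic_panel(pm, sorted(planted))
        roc = u.evaluate_panel(model, pm)
        assert roc.auc == model.training_roc.auc
        assert np.array_equal(roc.sensitivity, model.training_roc.sensitivity)

    def test_permuted_test_labels_give_null_auc(self):
        rng = np.random.default_rng(8)
        pm, planted = u.generate_profile(
            u.SyntheticConfig(n_case=500, n_control=500, m_compounds=10,
                              n_markers=1, n_contaminants=0, seed=9)
        )
        permuted = make_pm(pm.abundance, rng.permutation(pm.groups), pm.compounds)
        model = u.fit_logistic_panel(pm, sorted(planted))
        roc = u.evaluate_panel(model, permuted)
        se = np.sqrt((1000 + 1) / (12 * 500 * 500))
        assert abs(roc.auc - 0.5) < 3 * se

    def test_missing_marker_column_rejected(self):
        pm = make_pm([[1.0, 2.0]], labels(1, 1))
        model = u.PanelModel(
            marker_ids=["absent"], intercept=0.0,
            coefficients=np.array([1.0]), ridge=1e-6,
        )
        with pytest.raises(KeyError):
            u.evaluate_panel(model, pm)
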