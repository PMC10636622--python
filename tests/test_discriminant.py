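"""Wilks lambda, stepwise selection, LDA, LOOCV and metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sewersense as ss
from sewersense.discriminant import F_SENTINEL
from conftest import make_labeled_panel


def frame(values, columns=("v0",)):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    return pd.DataFrame(arr, columns=list(columns),
                        index=[f"p{i}" for i in range(arr.shape[0])])


class TestWilksLambda:
    def test_perfect_separation_gives_zero(self):
        data = frame([0.0, 0.0, 1.0, 1.0])
        assert ss.wilks_lambda(data, ["a", "a", "b", "b"], ["v0"]) == 0.0

    def test_hand_computed_univariate_example(self):
        # groups (0,2) vs (1,3): within SS = 4, total SS = 5 -> lambda = 0.8
        data = frame([0.0, 2.0, 1.0, 3.0])
        lam = ss.wilks_lambda(data, ["a", "a", "b", "b"], ["v0"])
        assert lam == pytest.approx(0.8)

    def test_empty_variable_set_is_one(self):
        data = frame([1.0, 2.0, 3.0, 4.0])
        assert ss.wilks_lambda(data, ["a", "a", "b", "b"], []) == 1.0

    def test_null_variables_at_large_n_near_one(self, rng):
        x, labels = make_labeled_panel(rng, n_west=400, n_east=400, effect=0.0)
        lam = ss.wilks_lambda(x, labels, list(x.columns))
        assert lam > 0.98

    def test_adding_a_variable_never_increases_lambda(self, rng):
        for _ in range(25):
            x, labels = make_labeled_panel(rng, n_vars=4, effect=rng.uniform(0, 2))
            cols = list(x.columns)
            rng.shuffle(cols)
            lam_prev = 1.0
            for k in range(1, len(cols) + 1):
                lam = ss.wilks_lambda(x, labels, cols[:k])
                assert lam <= lam_prev + 1e-12
                lam_prev = lam

    def test_singular_total_matrix_raises(self):
        data = frame([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]], columns=["a", "b"])
        with pytest.raises(ss.DegenerateDataError):
            ss.wilks_lambda(data, ["a", "a", "b", "b"], ["a", "b"])


class TestStepwiseSelection:
    def test_perfect_separator_enters_with_sentinel_f(self):
        data = frame([0.0, 0.0, 1.0, 1.0])
        selected, trace = ss.stepwise_select(data, ["a", "a", "b", "b"])
        assert selected == ["v0"]
        step = trace.steps[0]
        assert step.wilks_lambda == 0.0
        assert step.partial_f == F_SENTINEL
        assert step.p_value == 0.0

    def test_weak_variable_does_not_enter(self):
        # lambda = 0.8, F = ((4-0-2)/1)*(0.2/0.8) = 0.5 on (1,2), p = 0.553
        data = frame([0.0, 2.0, 1.0, 3.0])
        selected, trace = ss.stepwise_select(data, ["a", "a", "b", "b"])
        assert selected == []
        assert trace.steps == []
        assert stats.f.sf(0.5, 1, 2) == pytest.approx(0.5528, abs=1e-4)

    def test_lambda_nonincreasing_along_enter_steps(self, rng):
        x, labels = make_labeled_panel(rng, n_vars=5, effect=1.5)
        _, trace = ss.stepwise_select(x, labels)
        lams = [s.wilks_lambda for s in trace.steps if s.action == "enter"]
        assert all(b <= a + 1e-12 for a, b in zip(lams, lams[1:]))

    def test_invariant_to_row_order_and_column_scaling(self, rng):
        x, labels = make_labeled_panel(rng, n_vars=4, effect=1.2)
        sel, _ = ss.stepwise_select(x, labels)
        perm = rng.permutation(len(x))
        x2 = x.iloc[perm]
        labels2 = [labels[i] for i in perm]
        sel2, _ = ss.stepwise_select(x2, labels2)
        assert sel2 == sel
        x3 = x.copy()
        x3["v0"] = x3["v0"] * 1234.5
        sel3, _ = ss.stepwise_select(x3, labels)
        assert sel3 == sel

    def test_bad_thresholds_rejected(self, rng):
        x, labels = make_labeled_panel(rng)
        with pytest.raises(ss.ConfigError):
            ss.stepwise_select(x, labels, threshold_enter=0.0)
        with pytest.raises(ss.ConfigError):
            ss.stepwise_select(x, labels, threshold_stay=1.5)

    def test_entered_variables_respect_thresholds(self, rng):
        for _ in range(10):
            x, labels = make_labeled_panel(rng, n_vars=6, effect=rng.uniform(0.5, 2))
            _, trace = ss.stepwise_select(x, labels)
            for step in trace.steps:
                if step.action == "enter":
                    assert step.p_value <= 0.15
                else:
                    assert step.p_value > 0.15


class TestLda:
    def test_separated_classes_classified_perfectly(self):
        data = frame([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        labels = ["east"] * 3 + ["west"] * 3
        model = ss.fit_lda(data, labels, ["v0"])
        assert model.predict(data) == labels

    def test_equidistant_point_breaks_tie_to_first_sorted_class(self):
        data = frame([0.0, 0.2, -0.2, 1.0, 1.2, 0.8])
        labels = ["west", "west", "west", "east", "east", "east"]
        model = ss.fit_lda(data, labels, ["v0"])
        # midpoint 0.5 is equidistant under pooled covariance and equal priors
        assert model.predict(np.array([[0.5]])) == ["east"]

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        for _ in range(10):
            x, labels = make_labeled_panel(rng, n_west=8, n_east=7, n_vars=3,
                                           effect=rng.uniform(0, 2))
            model = ss.fit_lda(x, labels, list(x.columns))
            clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            clf.fit(x, labels)
            assert model.predict(x) == list(clf.predict(x))

    def test_empirical_error_matches_gaussian_closed_form(self):
        """Two bivariate normal classes at Mahalanobis distance 2: the
        discriminant's error rate approaches the closed form Phi(-delta/2)."""
        g = np.random.default_rng(77)
        n = 2000
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        delta = 2.0
        mean_shift = np.array([delta, 0.0])  # Mahalanobis distance delta
        l = np.linalg.cholesky(cov)
        shift = l @ mean_shift  # so that Sigma^-1/2 separation is exactly delta
        xa = g.standard_normal((n // 2, 2)) @ l.T
        xb = g.standard_normal((n // 2, 2)) @ l.T + shift
        x = pd.DataFrame(np.vstack([xa, xb]), columns=["v0", "v1"],
                         index=[f"p{i}" for i in range(n)])
        labels = ["east"] * (n // 2) + ["west"] * (n // 2)
        model = ss.fit_lda(x, labels, ["v0", "v1"])
        err = np.mean(np.asarray(model.predict(x)) != np.asarray(labels))
        bayes = stats.norm.cdf(-delta / 2)
        assert abs(err - bayes) < 3 * math.sqrt(bayes * (1 - bayes) / n)

    def test_singular_covariance_raises_with_ridge_escape(self):
        data = frame([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]],
                     columns=["a", "b"])
        labels = ["e", "e", "w", "w"]
        with pytest.raises(ss.DegenerateDataError):
            ss.fit_lda(data, labels, ["a", "b"])
        model = ss.fit_lda(data, labels, ["a", "b"], ridge=1e-6)
        assert model.predict(data) == labels

    def test_priors_options(self, rng):
        x, labels = make_labeled_panel(rng, n_west=8, n_east=4, effect=1.0)
        eq = ss.fit_lda(x, labels, ["v0"])
        prop = ss.fit_lda(x, labels, ["v0"], priors="proportional")
        assert np.allclose(eq.priors, [0.5, 0.5])
        assert np.allclose(prop.priors, [4 / 12, 8 / 12])  # classes sorted east, west


class TestLoocv:
    def test_perfectly_separated_panel_has_zero_errors(self):
        data = frame([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        labels = ["east"] * 3 + ["west"] * 3
        cm, preds = ss.loocv(data, labels, ["v0"])
        assert (cm.fp, cm.fn) == (0, 0)
        assert cm.total == 6

    def test_resubstitution_path_equals_whole_data_refit(self, rng):
        x, labels = make_labeled_panel(rng, effect=3.0)
        res = ss.StepwiseDiscriminantAnalysis(x, labels, candidates=["v0"]).fit()
        whole = ss.fit_lda(x, labels, res.selected)
        assert list(res.resub_predictions) == whole.predict(x)

    def test_permutation_null_mean_accuracy_never_beats_chance(self, rng):
        """With labels shuffled, mean LOOCV accuracy must not exceed the
        larger class share (no information leakage).  At n = 12 LOOCV under a
        permutation null is well known to be biased *downward* — single
        permutations can score far below chance, even 0 — so only the upward
        direction is a meaningful guarantee."""
        x, _ = make_labeled_panel(rng, n_west=7, n_east=5, effect=0.0)
        share = 7 / 12
        n_perm = 60
        accs = []
        for _ in range(n_perm):
            labels = list(rng.permutation(["west"] * 7 + ["east"] * 5))
            cm, _ = ss.loocv(x, labels, ["v0", "v1"])
            accs.append((cm.tp + cm.tn) / cm.total)
        se_mean = np.std(accs, ddof=1) / math.sqrt(n_perm)
        assert np.mean(accs) <= share + 3 * se_mean

    def test_single_class_training_fold_marked_unclassifiable(self):
        data = frame([0.0, 1.0, 2.0, 10.0, 11.0])
        labels = ["east", "east", "east", "west", "west"]
        cm, preds = ss.loocv(data, labels, ["v0"])
        # leaving out either western plant leaves only 1 west in training
        assert preds[["p3", "p4"]].isna().all()
        assert cm.n_unclassified == 2


class TestMetrics:
    def test_study_confusion_matrix_reproduces_reported_metrics(self):
        cm = ss.ConfusionMatrix(tp=7, fp=1, tn=4, fn=0, positive_class="west")
        m = ss.classification_metrics(cm)
        assert m.precision == pytest.approx(0.875)
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(14 / 15)
        assert m.accuracy == pytest.approx(11 / 12)

    def test_all_true_positives_gives_all_ones(self):
        m = ss.classification_metrics(ss.ConfusionMatrix(5, 0, 0, 0))
        assert (m.precision, m.sensitivity, m.f1, m.accuracy) == (1, 1, 1, 1)
        assert math.isnan(m.specificity)  # no negatives to get right

    def test_undefined_precision_flagged_not_zero(self):
        m = ss.classification_metrics(ss.ConfusionMatrix(0, 0, 3, 2))
        assert math.isnan(m.precision)
        assert math.isnan(m.f1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ss.DomainError):
            ss.classification_metrics(ss.ConfusionMatrix(0, 0, 0, 0))


class TestModelResultsSurface:
    def test_summary_renders_trace_and_metrics(self, rng):
        x, labels = make_labeled_panel(rng, n_west=7, n_east=5, n_vars=4, effect=2.5)
        res = ss.StepwiseDiscriminantAnalysis(x, labels).fit()
        text = res.summary()
        assert "Stepwise linear discriminant analysis" in text
        assert "Leave-one-out CV" in text
        d = res.to_dict()
        assert set(d["selected"]) == set(res.selected)
        assert d["confusion_loocv"]["positive_class"] == "west"
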