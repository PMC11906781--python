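"""PLS-DA, VIP, latent-variable selection, rDCV and permutation testing."""

import numpy as np
import pytest

import chemometab as cm
from chemometab.plsda import PLSDAError, _predict_truncated


def separable_1d(n_per=6):
    """Two classes separated on a single feature."""
    X = np.concatenate([np.full(n_per, -2.0), np.full(n_per, 2.0)])[:, None]
    X = X + np.linspace(-0.1, 0.1, 2 * n_per)[:, None]
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


class TestFitPredict:
    def test_separable_two_class_perfect_training_accuracy(self):
        X, y = separable_1d()
        m = cm.fit_plsda(X, y, 1)
        assert (cm.predict_classes(m, X) == y).all()

    def test_duplicated_features_leave_predictions_unchanged(self, rng):
        X = rng.standard_normal((16, 5))
        y = np.array(["A", "B", "C", "D"] * 4)
        m1 = cm.fit_plsda(X, y, 3)
        m2 = cm.fit_plsda(np.hstack([X, X]), y, 3)
        assert (cm.predict_classes(m1, X) == cm.predict_classes(m2, np.hstack([X, X]))).all()

    def test_invalid_inputs_rejected(self, rng):
        X, y = separable_1d()
        with pytest.raises(PLSDAError):
            cm.fit_plsda(X, y, 0)
        with pytest.raises(PLSDAError):
            cm.fit_plsda(X, np.array(["A"] * len(y)), 1)
        with pytest.raises(PLSDAError):
            cm.fit_plsda(X, y, 50)  # exceeds min(n-1, p)

    def test_tie_breaks_to_first_class_in_order(self):
        X, y = separable_1d()
        m = cm.fit_plsda(X, y, 1, class_order=["A", "B"])
        mid = np.array([[0.0]])  # equidistant: predicted responses tie
        yhat = m.pls.predict(mid)
        assert yhat[0, 0] == pytest.approx(yhat[0, 1])
        assert cm.predict_classes(m, mid)[0] == "A"

    def test_empty_matrix_gives_empty_labels(self):
        X, y = separable_1d()
        m = cm.fit_plsda(X, y, 1)
        assert len(cm.predict_classes(m, np.empty((0, 1)))) == 0

    def test_dimension_mismatch_rejected(self, rng):
        X, y = separable_1d()
        m = cm.fit_plsda(X, y, 1)
        with pytest.raises(PLSDAError, match="features"):
            cm.predict_classes(m, rng.standard_normal((2, 3)))

    def test_truncated_predictions_match_smaller_refit(self, rng):
        X = rng.standard_normal((20, 12))
        y = np.array(["A", "B", "C", "D"] * 5)
        full = cm.fit_plsda(X, y, 4)
        Xnew = rng.standard_normal((6, 12))
        for a in (1, 2, 3):
            sub = cm.fit_plsda(X, y, a)
            assert (_predict_truncated(full, Xnew, a) == cm.predict_classes(sub, Xnew)).all()


class TestVIP:
    def test_single_feature_vip_is_one(self):
        X, y = separable_1d()
        m = cm.fit_plsda(X, y, 1)
        assert cm.vip_scores(m) == pytest.approx([1.0])

    def test_mean_square_identity(self, rng):
        X = rng.standard_normal((24, 15))
        y = np.array(["A", "B", "C", "D"] * 6)
        for a in (1, 3, 5):
            v = cm.vip_scores(cm.fit_plsda(X, y, a))
            assert (v**2).sum() == pytest.approx(15, abs=1e-8)
            assert (v >= 0).all()

    def test_single_component_closed_form(self, rng):
        """With one latent variable, VIP_j = sqrt(p) * |w_j| / ||w||; for
        weights proportional to (0.8, 0.6) that is (1.1314, 0.8485)."""
        rng = np.random.default_rng(3)
        t = rng.standard_normal(200)
        X = np.outer(t, [0.8, 0.6]) + 1e-6 * rng.standard_normal((200, 2))
        y = np.where(t > 0, "A", "B")
        m = cm.fit_plsda(X, y, 1)
        w = m.x_weights[:, 0]
        assert abs(w / np.linalg.norm(w)) @ [1, 0] == pytest.approx(0.8, abs=1e-3)
        assert cm.vip_scores(m) == pytest.approx([1.13137, 0.84853], abs=2e-3)


class TestSelectNLV:
    def test_recovers_single_latent_direction(self, rng):
        t = np.repeat([-2.0, 2.0], 10) + 0.05 * rng.standard_normal(20)
        X = np.outer(t, rng.standard_normal(8)) + 0.05 * rng.standard_normal((20, 8))
        y = np.array(["A"] * 10 + ["B"] * 10)
        assert cm.select_nlv(X, y, max_A=5, folds=5, seed=0) == 1

    def test_max_A_one_returns_one(self):
        X, y = separable_1d()
        assert cm.select_nlv(X, y, max_A=1, folds=3, seed=0) == 1

    def test_tie_takes_smaller_A(self, rng):
        # perfectly separable: every A has zero CV error, so the tie rule decides
        t = np.repeat([-3.0, 3.0], 8)
        X = np.column_stack([t, rng.standard_normal(16), rng.standard_normal(16)])
        y = np.array(["A"] * 8 + ["B"] * 8)
        assert cm.select_nlv(X, y, max_A=2, folds=4, seed=1) == 1

    def test_validation(self):
        X, y = separable_1d()
        with pytest.raises(PLSDAError):
            cm.select_nlv(X, y, max_A=0)
        with pytest.raises(PLSDAError):
            cm.select_nlv(X, y, max_A=2, folds=1)


class TestClassificationMetrics:
    def test_diagonal_confusion_is_perfect(self):
        sens, spec, acc = cm.classification_metrics(np.diag([5, 3, 7]))
        assert np.allclose(sens, 100) and np.allclose(spec, 100) and acc == 100

    def test_two_class_hand_example(self):
        sens, spec, acc = cm.classification_metrics(np.array([[8, 2], [1, 9]]))
        assert np.allclose(sens, [80, 90])
        assert np.allclose(spec, [90, 80])
        assert acc == pytest.approx(85)

    def test_empty_class_row_reports_missing(self):
        sens, spec, acc = cm.classification_metrics(np.array([[0, 0], [1, 9]]))
        assert np.isnan(sens[0]) and sens[1] == 90

    def test_all_zero_matrix_errors(self):
        with pytest.raises(PLSDAError):
            cm.classification_metrics(np.zeros((3, 3)))


class TestRDCV:
    def test_high_accuracy_on_separable_classes(self, separable_data):
        X, y = separable_data
        res = cm.rdcv(X, y, outer=10, inner=10, repeats=3, max_A=5, seed=1)
        assert res.accuracy_mean >= 95.0

    def test_chance_level_on_permuted_labels(self, null_data):
        X, y_perm = null_data
        res = cm.rdcv(X, y_perm, outer=10, inner=10, repeats=3, max_A=5, seed=2)
        assert abs(res.accuracy_mean - 25.0) <= 10.0

    def test_same_seed_reproduces_result(self, separable_data):
        X, y = separable_data
        a = cm.rdcv(X, y, outer=10, inner=10, repeats=2, max_A=3, seed=9)
        b = cm.rdcv(X, y, outer=10, inner=10, repeats=2, max_A=3, seed=9)
        assert a.accuracy_mean == b.accuracy_mean and a.accuracy_sd == b.accuracy_sd
        assert np.array_equal(a.vip_frequency, b.vip_frequency)
        assert a.misclassification_matrix.equals(b.misclassification_matrix)

    def test_misclassification_rows_sum_to_100(self, separable_data):
        X, y = separable_data
        res = cm.rdcv(X, y, outer=10, inner=10, repeats=2, max_A=3, seed=4)
        assert np.allclose(res.misclassification_matrix.sum(axis=1), 100, atol=0.1)
        for d in (res.sensitivity_mean, res.specificity_mean):
            assert all(0 <= v <= 100 for v in d.values())

    def test_accuracy_monotone_in_effect_size(self):
        from conftest import simulate_prepped

        accs = []
        for effect in (0.0, 0.6, 2.0):
            X, y = simulate_prepped(seed=17, effect_size=effect, n_bio=8)
            accs.append(cm.rdcv(X, y, outer=8, inner=8, repeats=2, max_A=4, seed=3).accuracy_mean)
        assert accs[0] <= accs[1] <= accs[2]

    def test_validation(self, separable_data):
        X, y = separable_data
        with pytest.raises(PLSDAError):
            cm.rdcv(X, y, repeats=0)
        with pytest.raises(PLSDAError):
            cm.rdcv(X[:5], y[:5], outer=10)


class TestPermutation:
    def test_floor_p_value_on_separable_data(self, separable_data):
        X, y = separable_data
        res = cm.permutation_test(X, y, n_permutations=19, seed=1, max_A=3)
        assert res.p_value == pytest.approx(1 / 20)
        assert res.observed_metric > max(res.null_metrics)

    def test_null_calibration(self, null_data):
        """With y independent of X, p should be non-significant in most trials."""
        X, y_perm = null_data
        # subsample for speed: 40 samples keep folds balanced
        idx = np.arange(0, len(y_perm), 2)
        X, y_perm = X[idx], y_perm[idx]
        hits = 0
        trials = 5
        for s in range(trials):
            res = cm.permutation_test(X, y_perm, n_permutations=9, seed=100 + s, max_A=2)
            hits += res.p_value > 0.05
        assert hits >= trials - 1

    def test_validation(self, separable_data):
        X, y = separable_data
        with pytest.raises(PLSDAError):
            cm.permutation_test(X, y, n_permutations=0)
        with pytest.raises(PLSDAError):
            cm.permutation_test(X, y, n_permutations=5, metric="auc")
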