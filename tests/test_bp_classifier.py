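"""Softmax blood-pressure classifier: bins, split, fit, prediction, metrics."""

import numpy as np
import pytest

import scgpipe as sp
from scgpipe.bp_classifier import Hyperparams, _loss_grad, predict


class TestDiscretizeBP:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (119.9, 70.0, (0, 0)),
            (136.0, 70.0, (2, 0)),
            (121.0, 79.0, (1, 0)),
            (110.0, 80.0, (0, 1)),
            (120.0, 85.0, (1, 1)),
            (135.0, 86.0, (1, 2)),
            (150.0, 90.0, (2, 2)),
        ],
    )
    def test_clinical_bins_with_boundary_convention(self, sbp, dbp, expected):
        assert sp.discretize_bp(sbp, dbp) == expected

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sp.discretize_bp(0.0, 80.0)


class TestTrainTestSplit:
    def make_data(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = np.r_[np.zeros(34), np.ones(33), np.full(33, 2)].astype(int)
        return X, y

    def test_thirty_percent_test_fraction(self):
        X, y = self.make_data(100)
        X_tr, X_te, y_tr, y_te = sp.train_test_split(X, y, 0.3, seed=1)
        assert len(y_te) == 30
        assert len(y_tr) == 70

    def test_partition_disjoint_and_exhaustive(self):
        X, y = self.make_data(100)
        X_tr, X_te, _, _ = sp.train_test_split(X, y, 0.3, seed=2)
        combined = np.vstack([X_tr, X_te])
        assert combined.shape == X.shape
        assert {tuple(r) for r in combined} == {tuple(r) for r in X}

    def test_same_seed_gives_identical_partition(self):
        X, y = self.make_data(100)
        a = sp.train_test_split(X, y, 0.3, seed=3)
        b = sp.train_test_split(X, y, 0.3, seed=3)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_stratification_within_one_sample(self):
        X, y = self.make_data(100)
        _, _, _, y_te = sp.train_test_split(X, y, 0.3, seed=4)
        for c, n_c in ((0, 34), (1, 33), (2, 33)):
            ideal = 0.3 * n_c
            assert abs(np.sum(y_te == c) - ideal) <= 1

    def test_missing_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="classes"):
            sp.train_test_split(X, y, 0.3)


def separable_clusters(n_per=30, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    X = np.vstack([c + rng.normal(scale=0.3, size=(n_per, 2)) for c in centers])
    y = np.repeat([0, 1, 2], n_per)
    return X, y


class TestFitMultinomialLR:
    def test_uninformative_features_predict_priors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        y = np.array([0] * 150 + [1] * 90 + [2] * 60)
        model = sp.fit_multinomial_lr(X, y)
        proba = sp.predict_proba(model, X).mean(axis=0)
        assert proba == pytest.approx([0.5, 0.3, 0.2], abs=0.05)

    def test_separable_clusters_reach_perfect_training_accuracy(self):
        X, y = separable_clusters()
        model = sp.fit_multinomial_lr(X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_gradient_vanishes_at_reported_optimum(self):
        # finite-difference oracle on the regularized objective
        X, y = separable_clusters(n_per=15, seed=2)
        hyper = Hyperparams(max_iter=20000, tol=1e-12)
        model = sp.fit_multinomial_lr(X, y, hyper)
        Xs = (X - model.feature_mean) / model.feature_sd
        Y = np.zeros((len(y), 3))
        Y[np.arange(len(y)), y] = 1.0
        _, gW, gb, _ = _loss_grad(model.coef, model.intercept, Xs, Y, hyper.l2)
        eps = 1e-6
        W = model.coef.copy()
        for idx in [(0, 0), (1, 1), (2, 0)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            lp = _loss_grad(Wp, model.intercept, Xs, Y, hyper.l2)[0]
            lm = _loss_grad(Wm, model.intercept, Xs, Y, hyper.l2)[0]
            assert (lp - lm) / (2 * eps) == pytest.approx(gW[idx], abs=1e-4)
        assert np.max(np.abs(gW)) < 1e-4
        assert np.max(np.abs(gb)) < 1e-4

    def test_training_loss_monotone_nonincreasing(self):
        X, y = separable_clusters(seed=3)
        model = sp.fit_multinomial_lr(X, y)
        assert np.all(np.diff(model.loss_history) <= 1e-12)

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="finite"):
            sp.fit_multinomial_lr(X, np.array([0, 1, 2]))

    def test_agreement_with_reference_optimizer(self):
        """Fitted probabilities match scikit-learn's on the same objective."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        X, y = separable_clusters(n_per=40, seed=5)
        X += rng.normal(scale=1.0, size=X.shape)  # overlap so the fit matters
        hyper = Hyperparams(l2=1e-2, max_iter=50000, tol=1e-14)
        model = sp.fit_multinomial_lr(X, y, hyper)
        Xs = (X - model.feature_mean) / model.feature_sd
        ref = LogisticRegression(
            C=1.0 / (hyper.l2 * len(y)), solver="lbfgs", max_iter=5000, tol=1e-10
        ).fit(Xs, y)
        diff = np.abs(sp.predict_proba(model, X) - ref.predict_proba(Xs))
        assert diff.mean() < 1e-3


class TestPredictProba:
    def test_zero_weights_give_uniform_probabilities(self):
        model = sp.ModelWeights(
            coef=np.zeros((3, 2)),
            intercept=np.zeros(3),
            feature_mean=np.zeros(2),
            feature_sd=np.ones(2),
            hyper=Hyperparams(),
        )
        proba = sp.predict_proba(model, np.array([[1.0, -2.0]]))
        assert proba[0] == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_softmax_shift_invariance(self):
        from scgpipe.bp_classifier import _softmax

        z = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(_softmax(z), _softmax(z + 100.0))

    def test_dominant_logit_saturates(self):
        from scgpipe.bp_classifier import _softmax

        p = _softmax(np.array([[50.0, 0.0, 0.0]]))
        assert p[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        model = sp.ModelWeights(
            coef=rng.normal(size=(3, 4)),
            intercept=rng.normal(size=3),
            feature_mean=np.zeros(4),
            feature_sd=np.ones(4),
            hyper=Hyperparams(),
        )
        proba = sp.predict_proba(model, rng.normal(size=(50, 4)))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((proba > 0) & (proba < 1))

    def test_dimension_mismatch_rejected(self):
        model = sp.ModelWeights(
            coef=np.zeros((3, 2)),
            intercept=np.zeros(3),
            feature_mean=np.zeros(2),
            feature_sd=np.ones(2),
            hyper=Hyperparams(),
        )
        with pytest.raises(ValueError, match="dimension"):
            sp.predict_proba(model, np.zeros((5, 3)))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        proba = np.eye(3)[y] * 0.9 + 0.05
        report = sp.evaluate(y, proba)
        assert report.accuracy == 1.0
        assert np.array_equal(np.diag(report.confusion), [2, 2, 2])
        for k in range(3):
            assert report.roc[k].auc == pytest.approx(1.0)

    def test_random_probabilities_near_chance(self):
        rng = np.random.default_rng(7)
        n = 3000
        y = rng.integers(0, 3, size=n)
        proba = rng.dirichlet(np.ones(3), size=n)
        report = sp.evaluate(y, proba)
        assert report.accuracy == pytest.approx(1 / 3, abs=0.03)
        for k in range(3):
            assert report.roc[k].auc == pytest.approx(0.5, abs=0.03)

    def test_hand_built_confusion_matrix(self):
        # 6 samples enumerated by hand: true = [0,0,1,1,2,2],
        # predicted = [0,1,1,1,2,0]
        y = np.array([0, 0, 1, 1, 2, 2])
        proba = np.array(
            [
                [0.8, 0.1, 0.1],
                [0.2, 0.7, 0.1],
                [0.1, 0.8, 0.1],
                [0.3, 0.6, 0.1],
                [0.1, 0.2, 0.7],
                [0.6, 0.2, 0.2],
            ]
        )
        report = sp.evaluate(y, proba)
        expected = np.array([[1, 1, 0], [0, 2, 0], [1, 0, 1]])
        assert np.array_equal(report.confusion, expected)
        assert report.accuracy == pytest.approx(4 / 6)

    def test_auc_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        y = rng.integers(0, 3, size=200)
        proba = rng.dirichlet(np.ones(3), size=200)
        report = sp.evaluate(y, proba)
        for k in range(3):
            ref = roc_auc_score((y == k).astype(int), proba[:, k])
            assert report.roc[k].auc == pytest.approx(ref, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sp.evaluate(np.empty(0, dtype=int), np.empty((0, 3)))


def test_model_weights_json_round_trip():
    from scgpipe.bp_classifier import weights_from_dict, weights_to_dict

    X, y = separable_clusters(seed=9)
    model = sp.fit_multinomial_lr(X, y)
    restored = weights_from_dict(weights_to_dict(model))
    assert np.allclose(sp.predict_proba(restored, X), sp.predict_proba(model, X))
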