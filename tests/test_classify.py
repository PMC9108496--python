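"""Folds, metrics, CNN and baseline training behavior."""

from __future__ import annotations

import numpy as np
import pytest

from emofc.classify import (
    ModelConfig,
    compute_metrics,
    cross_validate,
    evaluate,
    make_folds,
    summarize_folds,
    train_baseline,
    train_cnn,
)
from emofc.containers import ConfusionCounts
from emofc.nn import build_model


class TestMakeFolds:
    def test_full_protocol_budget_1800_per_class_splits_1080_360_360(self):
        labels = np.array(["HVA"] * 1800 + ["LVA"] * 1800)
        folds = make_folds(labels, k=5, seed=0)
        assert len(folds) == 5
        for fold in folds:
            for cls in ("HVA", "LVA"):
                mask = labels == cls
                assert np.isin(fold.train, np.flatnonzero(mask)).sum() == 1080
                assert np.isin(fold.val, np.flatnonzero(mask)).sum() == 360
                assert np.isin(fold.test, np.flatnonzero(mask)).sum() == 360

    def test_small_set_keeps_the_same_ratios(self):
        labels = np.array(["HVA"] * 10 + ["LVA"] * 10)
        folds = make_folds(labels, k=5, seed=0)
        fold = folds[0]
        assert len(fold.train) == 12 and len(fold.val) == 4 and len(fold.test) == 4

    def test_union_of_test_parts_is_the_full_set(self):
        labels = np.array(["HVA"] * 23 + ["LVA"] * 27)
        folds = make_folds(labels, k=5, seed=3)
        tested = np.concatenate([f.test for f in folds])
        assert sorted(tested) == list(range(50))

    def test_roles_are_disjoint_within_each_fold(self):
        labels = np.array(["HVA"] * 20 + ["LVA"] * 20)
        for fold in make_folds(labels, k=5, seed=1):
            assert not set(fold.train) & set(fold.val)
            assert not set(fold.train) & set(fold.test)
            assert not set(fold.val) & set(fold.test)

    def test_fewer_than_three_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array(["HVA", "LVA"] * 5), k=2)

    def test_subject_grouped_folds_keep_each_subject_in_one_role(self):
        """With groups given, no subject's samples are split across roles."""
        labels = np.array((["HVA"] * 4 + ["LVA"] * 4) * 10)
        subjects = np.repeat(np.arange(10), 8)
        for fold in make_folds(labels, k=5, seed=0, groups=subjects):
            roles = {}
            for name, idx in (("train", fold.train), ("val", fold.val), ("test", fold.test)):
                for s in np.unique(subjects[idx]):
                    assert roles.setdefault(s, name) == name
        tested = np.concatenate([f.test for f in make_folds(labels, k=5, seed=0, groups=subjects)])
        assert sorted(tested) == list(range(80))


class TestMetrics:
    def test_perfect_counts_give_all_100(self):
        m = compute_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m.accuracy == m.sensitivity == m.specificity == m.f1 == 100.0

    def test_hand_computed_values(self):
        m = compute_metrics(ConfusionCounts(TP=30, FN=10, TN=35, FP=5))
        assert m.accuracy == pytest.approx(81.25)
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(87.5)
        assert m.f1 == pytest.approx(80.0)

    def test_degenerate_precision_reported_as_undefined(self):
        m = compute_metrics(ConfusionCounts(TP=0, FN=10, TN=10, FP=0))
        assert m.sensitivity == 0.0
        assert m.specificity == 100.0
        assert m.precision is None
        assert m.f1 is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_accuracy_invariant_to_class_swap_and_recall_complement(self):
        c = ConfusionCounts(TP=12, TN=30, FP=8, FN=14)
        swapped = ConfusionCounts(TP=c.TN, TN=c.TP, FP=c.FN, FN=c.FP)
        assert compute_metrics(c).accuracy == compute_metrics(swapped).accuracy
        m = compute_metrics(c)
        miss_rate = 100.0 * c.FN / (c.TP + c.FN)
        assert m.sensitivity + miss_rate == pytest.approx(100.0)


class _FixedPredictor:
    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def predict(self, X):
        return self.preds[: len(X)]


class TestEvaluate:
    def test_perfect_predictor_has_no_errors(self):
        y = np.array([1, 0, 1, 0])
        c = evaluate(_FixedPredictor(y), np.zeros((4, 1)), y)
        assert c.FP == c.FN == 0 and c.TP == 2 and c.TN == 2

    def test_constant_hva_predictor_on_balanced_set(self):
        y = np.array([1] * 5 + [0] * 5)
        c = evaluate(_FixedPredictor(np.ones(10, int)), np.zeros((10, 1)), y)
        assert (c.TP, c.FP, c.TN, c.FN) == (5, 5, 0, 0)

    def test_inverted_predictor_swaps_counts(self):
        y = np.array([1, 1, 0, 0])
        right = evaluate(_FixedPredictor(y), np.zeros((4, 1)), y)
        wrong = evaluate(_FixedPredictor(1 - y), np.zeros((4, 1)), y)
        assert (wrong.TP, wrong.TN, wrong.FP, wrong.FN) == (right.FN, right.FP, right.TN, right.TP)

    def test_unknown_string_label_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_FixedPredictor([0]), np.zeros((1, 1)), np.array(["XVA"]))


def _separable_images(n_per_class: int, rng: np.random.Generator):
    """Two-class image set separated by a strong mean shift in a row band."""
    X0 = rng.standard_normal((n_per_class, 3, 8, 20))
    X1 = rng.standard_normal((n_per_class, 3, 8, 20))
    X1[:, :, 2:5, :] += 2.0
    X = np.concatenate([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestCNN:
    def test_mini_cnn_learns_a_separable_set(self):
        """A linear classifier gets 100% here, so the CNN must exceed 95%."""
        X, y = _separable_images(60, np.random.default_rng(0))
        cfg = ModelConfig(scale="mini", epochs=5, seed=0)
        model = train_cnn(X, y, cfg)
        assert (model.predict(X) == y).mean() > 0.95

    def test_probabilities_sum_to_one(self):
        X, y = _separable_images(8, np.random.default_rng(1))
        model = train_cnn(X, y, ModelConfig(scale="mini", epochs=1, seed=0))
        np.testing.assert_allclose(model.predict_proba(X).sum(axis=1), 1.0, atol=1e-6)

    def test_permuted_labels_stay_near_chance(self):
        """With labels shuffled, test accuracy must hover around 50%."""
        rng = np.random.default_rng(2)
        accs = []
        for seed in range(5):
            X, y = _separable_images(40, rng)
            y = np.random.default_rng(seed).permutation(y)
            cfg = ModelConfig(scale="mini", epochs=3, seed=seed)
            model = train_cnn(X[:60], y[:60], cfg)
            accs.append((model.predict(X[60:]) == y[60:]).mean())
        assert 0.4 <= float(np.mean(accs)) <= 0.6

    def test_single_batch_overfit(self):
        """Capacity sanity check: 8 samples must be memorized."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 3, 8, 20))
        y = np.array([0, 1] * 4)
        model = train_cnn(X, y, ModelConfig(scale="mini", epochs=200, batch_size=8, seed=0))
        assert (model.predict(X) == y).mean() == 1.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_cnn(np.zeros((0, 3, 8, 20)), np.zeros(0, int), ModelConfig())

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        X, y = _separable_images(20, np.random.default_rng(9))
        model = train_cnn(X, y, ModelConfig(scale="mini", epochs=2, seed=1))
        model.save_weights(tmp_path / "ckpt.npz")
        fresh = build_model("mini", in_channels=3, seed=99)
        fresh.load_weights(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(fresh.predict_proba(X), model.predict_proba(X))

    def test_training_is_deterministic_under_fixed_seed(self):
        X, y = _separable_images(20, np.random.default_rng(4))
        cfg = ModelConfig(scale="mini", epochs=2, seed=7)
        p1 = train_cnn(X, y, cfg).predict_proba(X)
        p2 = train_cnn(X, y, cfg).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestArchitecture:
    def test_full_scale_layer_budget(self):
        """14 residual modules; 3 standard + 33 depthwise-separable convs."""
        model = build_model("full", seed=0)
        arch = model.architecture
        assert arch["modules"] == 14
        assert arch["standard_convs"] == 3
        assert arch["separable_convs"] == 33

    def test_mini_scale_has_two_separable_modules(self):
        arch = build_model("mini", seed=0).architecture
        assert arch["modules"] == 2
        assert arch["separable_convs"] == 4


class TestBaselines:
    @pytest.mark.parametrize("kind", ["svm", "rf", "logreg"])
    def test_baseline_learns_separable_set(self, kind):
        X, y = _separable_images(50, np.random.default_rng(5))
        model = train_baseline(kind, X[::2], y[::2], seed=0)
        assert (model.predict(X[1::2]) == y[1::2]).mean() > 0.9

    def test_baseline_chance_on_permuted_labels(self):
        rng = np.random.default_rng(6)
        X, y = _separable_images(50, rng)
        y = rng.permutation(y)
        model = train_baseline("svm", X[:60], y[:60], seed=0)
        acc = (model.predict(X[60:]) == y[60:]).mean()
        assert 0.3 <= acc <= 0.7

    def test_rf_deterministic_under_fixed_seed(self):
        X, y = _separable_images(30, np.random.default_rng(7))
        a = train_baseline("rf", X, y, seed=3).predict(X)
        b = train_baseline("rf", X, y, seed=3).predict(X)
        np.testing.assert_array_equal(a, b)


class TestCrossValidate:
    def test_summary_reports_mean_and_sd_over_folds(self):
        X, y = _separable_images(25, np.random.default_rng(8))
        result = cross_validate(
            X, y, lambda Xt, yt, Xv, yv: train_baseline("logreg", Xt, yt), k=5, seed=0
        )
        assert len(result.folds) == 5
        mean, sd = result.summary["accuracy"]
        assert 50.0 <= mean <= 100.0 and sd >= 0.0
        assert sum(c.total for c in result.folds) == 50

    def test_summarize_skips_undefined_metrics(self):
        from emofc.containers import MetricsReport

        reports = [
            MetricsReport(accuracy=50.0, sensitivity=0.0, specificity=100.0, precision=None, f1=None),
            MetricsReport(accuracy=70.0, sensitivity=40.0, specificity=100.0, precision=80.0, f1=53.3),
        ]
        summary = summarize_folds(reports)
        assert summary["accuracy"][0] == pytest.approx(60.0)
        assert summary["precision"][0] == pytest.approx(80.0)
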