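"""Warm-start forest and CNN estimators: growth schedule, determinism,
probability semantics, balanced resampling."""

import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from ecgqc.models import (
    CNNConfig,
    Conv2DClassifier,
    RFConfig,
    WarmStartForestClassifier,
    balanced_sample_indices,
    train_rf,
)


def separable_features(n_per_class=30, n_features=8, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(3):
        block = rng.normal(size=(n_per_class, n_features))
        block[:, c] += gap * (c + 1)
        X.append(block)
        y += [f"class{c}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestBalancedSampler:
    def test_equal_counts_at_minority_size(self):
        y = np.array([0] * 100 + [1] * 10 + [2] * 7)
        idx = balanced_sample_indices(y, np.random.default_rng(0))
        _, counts = np.unique(y[idx], return_counts=True)
        assert counts.tolist() == [7, 7, 7]

    def test_fresh_draws_differ_between_calls(self):
        y = np.array([0] * 500 + [1] * 10)
        rng = np.random.default_rng(0)
        a = set(balanced_sample_indices(y, rng))
        b = set(balanced_sample_indices(y, rng))
        assert a != b  # new majority-class examples each repetition


class TestWarmStartForest:
    def test_tree_count_is_repetitions_times_increment(self):
        X, y = separable_features()
        clf = WarmStartForestClassifier(
            estimators_increment=50, n_repetitions=20, random_state=0
        ).fit(X, y)
        assert clf.n_trees_total_ == 1000
        assert len(clf.forest_.estimators_) == 1000
        assert len(clf.step_metrics_) == 20

    def test_single_repetition(self):
        X, y = separable_features()
        clf = WarmStartForestClassifier(n_repetitions=1, random_state=0).fit(X, y)
        assert clf.n_trees_total_ == 50

    def test_seeded_determinism(self):
        X, y = separable_features()
        a = WarmStartForestClassifier(n_repetitions=3, random_state=7).fit(X, y)
        b = WarmStartForestClassifier(n_repetitions=3, random_state=7).fit(X, y)
        assert a.step_metrics_ == b.step_metrics_
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            WarmStartForestClassifier(n_repetitions=1).fit(X, ["a"] * 10)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(NotFittedError):
            WarmStartForestClassifier().predict_proba(np.zeros((2, 3)))

    def test_proba_rows_sum_to_one_and_vote_granularity(self):
        X, y = separable_features(gap=10.0)
        clf = WarmStartForestClassifier(n_repetitions=2, random_state=1).fit(X, y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        # perfectly separable classes give pure leaves: every probability is
        # a multiple of 1 / n_trees_used
        k = clf.n_trees_used_
        np.testing.assert_allclose(proba * k, np.round(proba * k), atol=1e-6)

    def test_best_checkpoint_selection(self):
        X, y = separable_features()
        clf = WarmStartForestClassifier(n_repetitions=4, random_state=3).fit(X, y)
        scores = [m["precision"] + m["recall"] for m in clf.step_metrics_]
        assert clf.best_step_ == int(np.argmax(scores)) + 1
        assert clf.n_trees_used_ == clf.best_step_ * 50

    def test_functional_wrapper(self):
        X, y = separable_features()
        model = train_rf(X, y, RFConfig(n_repetitions=2, seed=0))
        assert model.n_trees_total_ == 100


def separable_images(n_per_class=30, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(size=(n_per_class, 80, 100))
    X1 = rng.normal(size=(n_per_class, 80, 100))
    X1[:, 20:40, 30:60] += 5.0
    y = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    return np.concatenate([X0, X1]), y


class TestConv2DClassifier:
    def test_learns_separable_images(self):
        # slimmed feature maps keep this a unit test; the full-width topology
        # is exercised by the smoke suite
        X, y = separable_images()
        clf = Conv2DClassifier(
            feature_maps=(8, 6, 4), dense_sizes=(16, 8, 4),
            n_repetitions=3, epochs_per_step=10, patience_steps=3, random_state=0,
        ).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)
        assert 1 <= clf.n_steps_trained_ <= 3
        assert {"val_loss", "precision", "recall"} <= set(clf.step_metrics_[0])

    def test_single_class_rejected(self):
        X = np.zeros((4, 80, 100))
        with pytest.raises(ValueError):
            Conv2DClassifier().fit(X, ["a"] * 4)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            Conv2DClassifier().fit(np.zeros((4, 80)), ["a", "b", "a", "b"])

    def test_unfitted_rejected(self):
        with pytest.raises(NotFittedError):
            Conv2DClassifier().predict(np.zeros((1, 80, 100)))


class TestConfigs:
    def test_rf_config_invariants(self):
        with pytest.raises(ValueError):
            RFConfig(estimators_increment=0)
        with pytest.raises(ValueError):
            RFConfig(n_repetitions=0)

    def test_cnn_config_invariants(self):
        with pytest.raises(ValueError):
            CNNConfig(feature_maps=(25, 50, 100))
        with pytest.raises(ValueError):
            CNNConfig(dense_sizes=(16, 32))
        with pytest.raises(ValueError):
            CNNConfig(n_classes=4)
        cfg = CNNConfig()
        assert cfg.pool_sizes == (10, 5, 3) and cfg.pool_stride == 3
        assert cfg.activation_slope == 0.002 and cfg.l2_alpha == 0.01
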