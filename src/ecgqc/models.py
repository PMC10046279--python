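"""Classifier families for ECG quality: warm-start random forest and 2D CNN.

Both estimators follow the scikit-learn API (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, fitted attributes with a trailing
underscore) and share the balanced-resampling training scheme: the classes
are heavily imbalanced (~95% acceptable), so each of ``n_repetitions``
training steps draws a fresh equal-sized random sample per class — new draws
from the abundant acceptable class every step — holds out 20% of it for
validation, and records precision/recall.  The returned model is the step
checkpoint with the highest validation precision + recall.

The forest grows by ``estimators_increment`` trees per step (warm start,
bootstrap, out-of-bag scoring); the CNN is a fixed small topology — three
convolution blocks with feature maps (100, 50, 25), kernels (7, 5, 3),
average pooling (10, 5, 3) at stride 3, leaky rectification (slope 0.002),
dense stack (128, 64, 32, 16), softmax head — trained with Adam and early
stopping on validation loss with best-weight restoration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.metrics import precision_score, recall_score
from sklearn.preprocessing import LabelEncoder

from . import _cnn

__all__ = [
    "RFConfig",
    "CNNConfig",
    "balanced_sample_indices",
    "WarmStartForestClassifier",
    "Conv2DClassifier",
    "train_rf",
    "train_cnn",
    "predict_proba",
]


@dataclass
class RFConfig:
    """Hyperparameters of the incremental warm-start forest."""

    estimators_increment: int = 50
    bootstrap: bool = True
    use_oob: bool = True
    warm_start: bool = True
    n_repetitions: int = 20
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimators_increment <= 0:
            raise ValueError("estimators_increment must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class CNNConfig:
    """Hyperparameters of the small 2D CNN."""

    feature_maps: Tuple[int, ...] = (100, 50, 25)
    kernel_sizes: Tuple[int, ...] = (7, 5, 3)
    pool_sizes: Tuple[int, ...] = (10, 5, 3)
    pool_stride: int = 3
    activation_slope: float = 0.002
    dropout_keep: float = 0.5
    dense_sizes: Tuple[int, ...] = (128, 64, 32, 16)
    l2_alpha: float = 0.01
    learning_rate: float = 0.001
    batch_size: int = 50
    n_classes: int = 3
    n_repetitions: int = 20
    # 20 repetitions x 5 epochs = 100 total training epochs at the defaults
    epochs_per_step: int = 5
    patience_steps: int = 1
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.feature_maps) != sorted(self.feature_maps, reverse=True):
            raise ValueError("feature_maps must be strictly decreasing")
        if list(self.dense_sizes) != sorted(self.dense_sizes, reverse=True):
            raise ValueError("dense_sizes must be strictly decreasing")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")


def balanced_sample_indices(
    y: np.ndarray, rng: np.random.Generator, n_per_class: Optional[int] = None
) -> np.ndarray:
    """Fresh equal-count random draw per class (without replacement per class).

    *n_per_class* defaults to the minority-class count; classes with more
    members are randomly undersampled, so the abundant class contributes new
    examples on every call.
    """
    classes, counts = np.unique(y, return_counts=True)
    if n_per_class is None:
        n_per_class = int(counts.min())
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        take = min(n_per_class, len(members))
        idx.append(rng.choice(members, size=take, replace=False))
    out = np.concatenate(idx)
    rng.shuffle(out)
    return out


def _val_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float]:
    p = precision_score(y_true, y_pred, average="macro", zero_division=0)
    r = recall_score(y_true, y_pred, average="macro", zero_division=0)
    return float(p), float(r)


class WarmStartForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest grown incrementally over balanced resampling steps.

    Each step draws a fresh balanced sample, holds out 20% for validation,
    and adds ``estimators_increment`` trees to the warm-started forest, so
    later trees see new draws from the abundant class.  After
    ``n_repetitions`` steps the forest has ``n_repetitions x increment``
    trees; prediction uses the leading trees up to the step whose validation
    precision + recall was highest (all trees when ``select_best=False``).
    """

    def __init__(
        self,
        estimators_increment: int = 50,
        n_repetitions: int = 20,
        bootstrap: bool = True,
        use_oob: bool = True,
        validation_fraction: float = 0.2,
        select_best: bool = True,
        random_state: Optional[int] = None,
    ):
        self.estimators_increment = estimators_increment
        self.n_repetitions = n_repetitions
        self.bootstrap = bootstrap
        self.use_oob = use_oob
        self.validation_fraction = validation_fraction
        self.select_best = select_best
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if self.estimators_increment <= 0 or self.n_repetitions < 1:
            raise ValueError("estimators_increment and n_repetitions must be positive")
        self._le = LabelEncoder().fit(y)
        self.classes_ = self._le.classes_
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least two classes")
        y_enc = self._le.transform(y)

        rng = np.random.default_rng(self.random_state)
        forest = RandomForestClassifier(
            n_estimators=0,
            warm_start=True,
            bootstrap=self.bootstrap,
            oob_score=self.use_oob and self.bootstrap,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        self.step_metrics_: List[dict] = []
        for step in range(self.n_repetitions):
            idx = balanced_sample_indices(y_enc, rng)
            n_val = max(1, int(round(self.validation_fraction * len(idx))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if len(np.unique(y_enc[tr_idx])) < len(self.classes_):
                tr_idx = idx  # tiny samples: fall back to the full balanced draw
            forest.set_params(n_estimators=(step + 1) * self.estimators_increment)
            forest.fit(X[tr_idx], y_enc[tr_idx])
            p, r = _val_metrics(y_enc[val_idx], forest.predict(X[val_idx]))
            self.step_metrics_.append(
                {"step": step + 1, "n_trees": forest.n_estimators,
                 "precision": p, "recall": r}
            )
        self.forest_ = forest
        self.n_trees_total_ = forest.n_estimators
        best = int(np.argmax([m["precision"] + m["recall"] for m in self.step_metrics_]))
        self.best_step_ = best + 1
        self.n_trees_used_ = (
            self.best_step_ * self.estimators_increment
            if self.select_best
            else self.n_trees_total_
        )
        if self.use_oob and self.bootstrap:
            self.oob_score_ = float(forest.oob_score_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "forest_"):
            raise NotFittedError("this WarmStartForestClassifier is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        trees = self.forest_.estimators_[: self.n_trees_used_]
        proba = np.mean([t.predict_proba(X) for t in trees], axis=0)
        return proba

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class Conv2DClassifier(BaseEstimator, ClassifierMixin):
    """Small 2D CNN on (80, 100) input images, 2- or 3-class softmax head.

    Trains with the balanced-resampling scheme: each step draws a fresh
    balanced sample, holds out 20%, runs ``epochs_per_step`` Adam epochs,
    and snapshots the weights.  Training stops early when validation loss
    has not improved for ``patience_steps`` steps; the weights restored at
    the end are those of the step with the highest validation
    precision + recall.
    """

    def __init__(
        self,
        feature_maps: Tuple[int, ...] = (100, 50, 25),
        kernel_sizes: Tuple[int, ...] = (7, 5, 3),
        pool_sizes: Tuple[int, ...] = (10, 5, 3),
        pool_stride: int = 3,
        activation_slope: float = 0.002,
        dropout_keep: float = 0.5,
        dense_sizes: Tuple[int, ...] = (128, 64, 32, 16),
        l2_alpha: float = 0.01,
        learning_rate: float = 0.001,
        batch_size: int = 50,
        n_repetitions: int = 20,
        epochs_per_step: int = 5,
        patience_steps: int = 1,
        validation_fraction: float = 0.2,
        random_state: Optional[int] = None,
    ):
        self.feature_maps = feature_maps
        self.kernel_sizes = kernel_sizes
        self.pool_sizes = pool_sizes
        self.pool_stride = pool_stride
        self.activation_slope = activation_slope
        self.dropout_keep = dropout_keep
        self.dense_sizes = dense_sizes
        self.l2_alpha = l2_alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_repetitions = n_repetitions
        self.epochs_per_step = epochs_per_step
        self.patience_steps = patience_steps
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- topology ----------------------------------------------------------
    def _build(self, input_shape: Tuple[int, int], n_classes: int,
               rng: np.random.Generator) -> _cnn.Network:
        h, w = input_shape
        c = 1
        layers: List[_cnn.Layer] = []
        for maps, k, pool in zip(self.feature_maps, self.kernel_sizes, self.pool_sizes):
            layers.append(_cnn.Conv2D(c, maps, k, rng))
            layers.append(_cnn.LeakyReLU(self.activation_slope))
            h, w, c = h - k + 1, w - k + 1, maps
            layers.append(_cnn.AvgPool2D(pool, self.pool_stride))
            h = (h - pool) // self.pool_stride + 1
            w = (w - pool) // self.pool_stride + 1
            if h < 1 or w < 1:
                raise ValueError("input too small for the configured topology")
        layers.append(_cnn.Flatten())
        n_in = h * w * c
        for n_out in self.dense_sizes:
            layers.append(_cnn.Dense(n_in, n_out, rng))
            layers.append(_cnn.LeakyReLU(self.activation_slope))
            layers.append(_cnn.Dropout(self.dropout_keep))
            n_in = n_out
        layers.append(_cnn.Dense(n_in, n_classes, rng))
        return _cnn.Network(layers, l2_alpha=self.l2_alpha, lr=self.learning_rate,
                            seed=int(rng.integers(0, 2**31 - 1)))

    # -- training ----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, height, width) images, got shape {X.shape}")
        y = np.asarray(y)
        self._le = LabelEncoder().fit(y)
        self.classes_ = self._le.classes_
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least two classes")
        y_enc = self._le.transform(y)
        n_classes = len(self.classes_)

        # normalise image intensities once, from the training data
        self.scale_ = float(np.std(X)) or 1.0
        self.offset_ = float(np.mean(X))
        Xn = ((X - self.offset_) / self.scale_)[..., None]  # NHWC

        rng = np.random.default_rng(self.random_state)
        net = self._build(X.shape[1:], n_classes, rng)

        best_val_loss = np.inf
        stale = 0
        self.step_metrics_: List[dict] = []
        snapshots: List[List[np.ndarray]] = []
        for step in range(self.n_repetitions):
            idx = balanced_sample_indices(y_enc, rng)
            n_val = max(1, int(round(self.validation_fraction * len(idx))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if len(np.unique(y_enc[tr_idx])) < n_classes:
                tr_idx = idx
            for _ in range(self.epochs_per_step):
                order = rng.permutation(tr_idx)
                for lo in range(0, len(order), self.batch_size):
                    batch = order[lo : lo + self.batch_size]
                    net.train_batch(Xn[batch], y_enc[batch])
            val_loss = net.loss(Xn[val_idx], y_enc[val_idx])
            pred = np.argmax(net.forward(Xn[val_idx]), axis=1)
            p, r = _val_metrics(y_enc[val_idx], pred)
            self.step_metrics_.append(
                {"step": step + 1, "val_loss": val_loss, "precision": p, "recall": r}
            )
            snapshots.append(net.get_weights())
            if val_loss < best_val_loss - 1e-6:
                best_val_loss = val_loss
                stale = 0
            else:
                stale += 1
                if stale >= self.patience_steps:
                    break
        self.n_steps_trained_ = len(self.step_metrics_)
        best = int(np.argmax([m["precision"] + m["recall"] for m in self.step_metrics_]))
        self.best_step_ = best + 1
        net.set_weights(snapshots[best])
        self.net_ = net
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise NotFittedError("this Conv2DClassifier is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        Xn = ((X - self.offset_) / self.scale_)[..., None]
        # bound memory: run the forward pass in batches
        out = [
            self.net_.forward(Xn[lo : lo + self.batch_size])
            for lo in range(0, len(Xn), self.batch_size)
        ]
        return np.concatenate(out) if out else np.empty((0, len(self.classes_)))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# thin functional wrappers


def train_rf(features: np.ndarray, labels: Sequence, cfg: RFConfig = RFConfig()
             ) -> WarmStartForestClassifier:
    """Train the warm-start forest on a feature matrix with balanced resampling."""
    clf = WarmStartForestClassifier(
        estimators_increment=cfg.estimators_increment,
        n_repetitions=cfg.n_repetitions,
        bootstrap=cfg.bootstrap,
        use_oob=cfg.use_oob,
        validation_fraction=cfg.validation_fraction,
        random_state=cfg.seed,
    )
    return clf.fit(features, labels)


def train_cnn(images: np.ndarray, labels: Sequence, cfg: CNNConfig = CNNConfig()
              ) -> Conv2DClassifier:
    """Train the 2D CNN on (n, 80, 100) images with balanced resampling."""
    clf = Conv2DClassifier(
        feature_maps=cfg.feature_maps,
        kernel_sizes=cfg.kernel_sizes,
        pool_sizes=cfg.pool_sizes,
        pool_stride=cfg.pool_stride,
        activation_slope=cfg.activation_slope,
        dropout_keep=cfg.dropout_keep,
        dense_sizes=cfg.dense_sizes,
        l2_alpha=cfg.l2_alpha,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        n_repetitions=cfg.n_repetitions,
        epochs_per_step=cfg.epochs_per_step,
        patience_steps=cfg.patience_steps,
        validation_fraction=cfg.validation_fraction,
        random_state=cfg.seed,
    )
    return clf.fit(images, labels)


def predict_proba(model, X) -> np.ndarray:
    """Class-probability rows from any fitted quality classifier."""
    return model.predict_proba(X)
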