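"""One-step 3-class and two-step binary-sequential classification logic.

The two-step cascade addresses the extreme class imbalance of monitor data
(~95% acceptable): classifier 1 separates *acceptable* from everything else
and is trained only on acceptable + unacceptable segments — the two classes
that differ most clearly; classifier 2 separates *unacceptable* from
*uncertain* among the remainder and is trained only on those two classes.
At inference, classifier 2 is consulted only when classifier 1 says "other".

Both binary steps decide at probability threshold 0.5; the 3-class route
takes the argmax with the fixed tie-break order acceptable > unacceptable >
uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import NotFittedError

from .models import WarmStartForestClassifier, balanced_sample_indices
from .segment import LABEL_ORDER, QualityLabel

__all__ = [
    "CascadeModel",
    "OneStepClassifier",
    "TwoStepCascadeClassifier",
    "one_step_classify",
    "two_step_classify",
    "build_training_sets",
    "LABELS",
]

#: canonical string labels, in tie-break / confusion-matrix order
LABELS = tuple(lbl.value for lbl in LABEL_ORDER)
ACCEPTABLE, UNACCEPTABLE, UNCERTAIN = LABELS

#: decision threshold of both binary cascade steps
STEP_THRESHOLD = 0.5


def _as_str_labels(y) -> np.ndarray:
    out = np.array([lbl.value if isinstance(lbl, QualityLabel) else str(lbl) for lbl in y])
    unknown = set(out) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown quality labels: {sorted(unknown)}")
    return out


def _proba_in_canonical_order(model, X, subset: Sequence[str]) -> np.ndarray:
    """predict_proba columns reordered to the canonical label order *subset*."""
    proba = model.predict_proba(X)
    cols = {str(c): j for j, c in enumerate(model.classes_)}
    missing = [c for c in subset if c not in cols]
    if missing:
        raise ValueError(f"model lacks classes {missing}; has {list(model.classes_)}")
    return proba[:, [cols[c] for c in subset]]


# ---------------------------------------------------------------------------
# one-step


class OneStepClassifier(BaseEstimator, ClassifierMixin):
    """3-class quality classifier: a base estimator plus the fixed decision rule.

    ``base`` is any sklearn-style classifier (default: the warm-start
    forest); it is cloned in ``fit`` and trained on all three classes with
    its internal balanced resampling.  Prediction is the probability argmax
    with ties broken in the order acceptable > unacceptable > uncertain.
    """

    def __init__(self, base: Optional[BaseEstimator] = None,
                 random_state: Optional[int] = None):
        self.base = base
        self.random_state = random_state

    def fit(self, X, y):
        y = _as_str_labels(y)
        if set(y) != set(LABELS):
            raise ValueError("one-step training data must contain all three classes")
        base = clone(self.base) if self.base is not None else WarmStartForestClassifier(
            random_state=self.random_state
        )
        if self.base is not None and self.random_state is not None and (
            "random_state" in base.get_params()
        ):
            base.set_params(random_state=self.random_state)
        self.model_ = base.fit(np.asarray(X), y)
        self.classes_ = np.array(LABELS)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise NotFittedError("OneStepClassifier is not fitted")
        return _proba_in_canonical_order(self.model_, X, LABELS)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # first max wins ties


def one_step_classify(model, X) -> np.ndarray:
    """Labels from a fitted 3-class model: canonical-order argmax, fixed tie-break."""
    if hasattr(model, "predict_proba") and hasattr(model, "classes_"):
        proba = _proba_in_canonical_order(model, np.asarray(X), LABELS)
    else:
        proba = np.asarray(X)  # already probability rows in canonical order
    return np.array(LABELS)[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# two-step


@dataclass
class CascadeModel:
    """Ordered pair of fitted binary models implementing the two-step logic."""

    step1: BaseEstimator  # acceptable vs unacceptable (used as acceptable vs other)
    step2: BaseEstimator  # unacceptable vs uncertain


class TwoStepCascadeClassifier(BaseEstimator, ClassifierMixin):
    """Binary-sequential quality classifier.

    ``fit`` routes the training data per the cascade contract: step 1 sees
    only acceptable + unacceptable segments, step 2 only unacceptable +
    uncertain.  Each step's estimator balances classes internally by fresh
    random undersampling per training repetition.
    """

    def __init__(self, step1: Optional[BaseEstimator] = None,
                 step2: Optional[BaseEstimator] = None,
                 random_state: Optional[int] = None):
        self.step1 = step1
        self.step2 = step2
        self.random_state = random_state

    def _make_step(self, template: Optional[BaseEstimator], seed_offset: int):
        est = clone(template) if template is not None else WarmStartForestClassifier()
        if "random_state" in est.get_params() and self.random_state is not None:
            est.set_params(random_state=self.random_state + seed_offset)
        return est

    def fit(self, X, y):
        X = np.asarray(X)
        y = _as_str_labels(y)
        for cls in LABELS:
            if not (y == cls).any():
                raise ValueError(f"cascade training requires class {cls!r}")
        m1 = (y == ACCEPTABLE) | (y == UNACCEPTABLE)
        m2 = (y == UNACCEPTABLE) | (y == UNCERTAIN)
        step1 = self._make_step(self.step1, 1).fit(X[m1], y[m1])
        step2 = self._make_step(self.step2, 2).fit(X[m2], y[m2])
        self.cascade_ = CascadeModel(step1=step1, step2=step2)
        self.classes_ = np.array(LABELS)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Composed class probabilities: p(other) is split by the step-2 model."""
        if not hasattr(self, "cascade_"):
            raise NotFittedError("TwoStepCascadeClassifier is not fitted")
        X = np.asarray(X)
        p_acc = _proba_in_canonical_order(self.cascade_.step1, X, [ACCEPTABLE])[:, 0]
        p2 = _proba_in_canonical_order(self.cascade_.step2, X, [UNACCEPTABLE, UNCERTAIN])
        other = 1.0 - p_acc
        return np.column_stack([p_acc, other * p2[:, 0], other * p2[:, 1]])

    def predict(self, X) -> np.ndarray:
        return two_step_classify(self.cascade_ if hasattr(self, "cascade_") else None, X)


def two_step_classify(cascade: Optional[CascadeModel], X) -> np.ndarray:
    """Sequential decision: step 1 at threshold 0.5, step 2 only for "other".

    A segment with step-1 acceptable probability >= 0.5 is *acceptable* and
    step 2 is never consulted for it; otherwise step 2 labels it
    *unacceptable* (probability >= 0.5) or *uncertain*.
    """
    if cascade is None or not hasattr(cascade.step1, "classes_"):
        raise NotFittedError("cascade steps are not fitted")
    X = np.asarray(X)
    out = np.full(len(X), ACCEPTABLE, dtype=object)
    p_acc = _proba_in_canonical_order(cascade.step1, X, [ACCEPTABLE])[:, 0]
    other = p_acc < STEP_THRESHOLD
    if other.any():
        p_unacc = _proba_in_canonical_order(
            cascade.step2, X[other], [UNACCEPTABLE]
        )[:, 0]
        out[other] = np.where(p_unacc >= STEP_THRESHOLD, UNACCEPTABLE, UNCERTAIN)
    return out.astype(str)


# ---------------------------------------------------------------------------
# training-set routing


def build_training_sets(
    y, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index sets for the three classifiers, balanced by seeded undersampling.

    Returns ``(idx_3class, idx_step1, idx_step2)`` into the dataset:
    the 3-class set balances all three classes to the minority count; the
    step-1 set holds acceptable + unacceptable (balanced between the two);
    the step-2 set holds unacceptable + uncertain (balanced).  Raises if a
    required class is empty.
    """
    y = _as_str_labels(y)
    rng = np.random.default_rng(seed)
    for cls in LABELS:
        if not (y == cls).any():
            raise ValueError(f"class {cls!r} is empty; cannot build training sets")

    def _balanced(mask: np.ndarray) -> np.ndarray:
        sub = np.flatnonzero(mask)
        rel = balanced_sample_indices(y[sub], rng)
        return np.sort(sub[rel])

    idx_3 = _balanced(np.isin(y, LABELS))
    idx_s1 = _balanced(np.isin(y, [ACCEPTABLE, UNACCEPTABLE]))
    idx_s2 = _balanced(np.isin(y, [UNACCEPTABLE, UNCERTAIN]))
    return idx_3, idx_s1, idx_s2
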