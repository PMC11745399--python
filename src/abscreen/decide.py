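"""Decision rules: strict all-criteria-true and a random-forest combiner.

Two ways to turn a records x criteria Boolean verdict matrix into
include/exclude decisions:

* :class:`AllCriteriaTrueClassifier` — a record is included only when
  every criterion verdict is true. Stringent by construction: one false
  criterion excludes.
* :class:`RandomForestCriterionCombiner` — learns how criteria jointly
  predict the human screening-1 decision, so a record can survive a
  single false criterion if the others carry enough signal. Evaluated
  with out-of-fold predictions from stratified k-fold cross-validation,
  where k adapts to the minority class size (min 2, max 5) so each fold
  holds both classes.

Both are scikit-learn estimators (``fit``/``predict``,
``get_params``/``set_params``) and compose with sklearn pipelines; the
module-level functions :func:`all_true_rule` and :func:`rf_out_of_fold`
are thin wrappers that additionally handle failed-status records (they
always decide False and are excluded from training, staying in the
residual human-workload pool).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ConfigurationError, InsufficientClassError
from .judge import VerdictSet

__all__ = [
    "CriteriaMatrix",
    "DecisionVector",
    "RFConfig",
    "AllCriteriaTrueClassifier",
    "RandomForestCriterionCombiner",
    "adaptive_fold_count",
    "all_true_rule",
    "rf_out_of_fold",
]


@dataclass
class CriteriaMatrix:
    """Records x criteria Boolean verdicts plus per-record processing status."""

    record_ids: list[str]
    criterion_keys: list[str]
    values: np.ndarray  # bool, shape (n_records, n_criteria)
    status: list[str] = field(default_factory=list)  # "ok" | "failed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not self.status:
            self.status = ["ok"] * len(self.record_ids)
        n, c = self.values.shape if self.values.ndim == 2 else (len(self.values), 0)
        if n != len(self.record_ids) or c != len(self.criterion_keys):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.record_ids)} ids x {len(self.criterion_keys)} keys"
            )
        if len(self.status) != n:
            raise ValueError("status length does not match record count")

    @property
    def ok_mask(self) -> np.ndarray:
        return np.array([s == "ok" for s in self.status], dtype=bool)

    @classmethod
    def from_verdict_sets(
        cls, verdict_sets: Sequence[VerdictSet], criterion_keys: Sequence[str]
    ) -> "CriteriaMatrix":
        keys = list(criterion_keys)
        return cls(
            record_ids=[vs.record_id for vs in verdict_sets],
            criterion_keys=keys,
            values=np.array([vs.values(keys) for vs in verdict_sets], dtype=bool),
            status=[vs.status for vs in verdict_sets],
        )


@dataclass
class DecisionVector:
    """One include/exclude decision per record, tagged with the rule used."""

    record_ids: list[str]
    decision: np.ndarray  # bool per record
    rule: str  # "all_true" | "random_forest"

    def __post_init__(self) -> None:
        self.decision = np.asarray(self.decision, dtype=bool)
        if len(self.decision) != len(self.record_ids):
            raise ValueError("one decision per record required")

    def as_dict(self) -> dict[str, bool]:
        return dict(zip(self.record_ids, self.decision.tolist()))


@dataclass
class RFConfig:
    n_estimators: int = 100
    class_weight: str = "balanced"
    min_folds: int = 2
    max_folds: int = 5
    seed: int = 28


def adaptive_fold_count(
    class_counts: tuple[int, int], min_folds: int = 2, max_folds: int = 5
) -> int:
    """Cross-validation fold count adapted to the minority class.

    k = min(max_folds, max(min_folds, min class size)), so every stratified
    fold contains at least one member of each class. A class with fewer
    than ``min_folds`` members cannot be stratified at all and raises.
    """
    smallest = min(class_counts)
    if smallest < min_folds:
        raise InsufficientClassError(
            f"minority class has {smallest} member(s); need >= {min_folds} "
            "for stratified cross-validation"
        )
    return min(max_folds, max(min_folds, smallest))


class AllCriteriaTrueClassifier(ClassifierMixin, BaseEstimator):
    """Include a record iff every criterion verdict is true.

    A rule, not a learned model: ``fit`` only records the feature count.
    Rejects zero-column input (vacuous truth would include everything).
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, ensure_min_features=0, dtype=None)
        if X.shape[1] == 0:
            raise ConfigurationError("cannot decide with zero criteria")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=None)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("criterion count changed between fit and predict")
        return np.asarray(X, dtype=bool).all(axis=1)


class RandomForestCriterionCombiner(ClassifierMixin, BaseEstimator):
    """Random forest over criterion verdicts predicting the screening decision.

    100 trees with class weights inversely proportional to class
    frequencies (screening corpora are heavily imbalanced). ``fit`` trains
    on all rows; :meth:`cross_val_decisions` yields out-of-fold
    predictions from stratified k-fold CV with adaptive k, so every record
    is predicted by a forest trained without its own fold.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        class_weight: str = "balanced",
        min_folds: int = 2,
        max_folds: int = 5,
        random_state: int = 28,
    ) -> None:
        self.n_estimators = n_estimators
        self.class_weight = class_weight
        self.min_folds = min_folds
        self.max_folds = max_folds
        self.random_state = random_state

    def _forest(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            class_weight=self.class_weight,
            random_state=self.random_state,
        )

    def _check_Xy(self, X, y):
        X = check_array(X, dtype=None)
        y = np.asarray(y, dtype=bool)
        if len(y) != X.shape[0]:
            raise ValueError("labels do not align with matrix rows")
        counts = (int((~y).sum()), int(y.sum()))
        if min(counts) < 1:
            raise InsufficientClassError("both classes must be present")
        if np.asarray(X, dtype=bool).all(axis=0).any() or (~np.asarray(X, dtype=bool)).all(axis=0).any():
            warnings.warn(
                "criteria matrix has constant column(s); the forest cannot "
                "use them", UserWarning, stacklevel=2,
            )
        return X, y, counts

    def fit(self, X, y):
        X, y, counts = self._check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        self.n_folds_ = adaptive_fold_count(counts, self.min_folds, self.max_folds)
        self.forest_ = self._forest().fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.forest_.predict(check_array(X, dtype=None)).astype(bool)

    def predict_proba(self, X):
        check_is_fitted(self)
        return self.forest_.predict_proba(check_array(X, dtype=None))

    def cross_val_decisions(self, X, y) -> np.ndarray:
        """Out-of-fold predictions; each record held out exactly once."""
        X, y, counts = self._check_Xy(X, y)
        k = adaptive_fold_count(counts, self.min_folds, self.max_folds)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.random_state)
        pred = cross_val_predict(self._forest(), X, y, cv=cv)
        return np.asarray(pred, dtype=bool)


def all_true_rule(matrix: CriteriaMatrix) -> DecisionVector:
    """Strict conjunction over each record's criterion verdicts.

    Failed-status records decide False regardless of their (all-false)
    rows, keeping them in the residual-workload pool.
    """
    if len(matrix.criterion_keys) == 0:
        raise ConfigurationError("cannot decide with zero criteria")
    if len(matrix.record_ids) == 0:
        raise ConfigurationError("empty criteria matrix")
    clf = AllCriteriaTrueClassifier().fit(matrix.values)
    decision = clf.predict(matrix.values) & matrix.ok_mask
    return DecisionVector(record_ids=list(matrix.record_ids), decision=decision, rule="all_true")


def rf_out_of_fold(
    matrix: CriteriaMatrix,
    labels: Sequence[bool] | np.ndarray,
    config: RFConfig | None = None,
) -> DecisionVector:
    """Out-of-fold random-forest decisions from criterion verdicts.

    Failed-status records are excluded from training and decided False;
    ok records receive the prediction of a forest trained without their
    fold. A fixed seed reproduces decisions exactly.
    """
    config = config or RFConfig()
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(matrix.record_ids):
        raise ValueError("labels do not align with matrix rows")
    ok = matrix.ok_mask
    combiner = RandomForestCriterionCombiner(
        n_estimators=config.n_estimators,
        class_weight=config.class_weight,
        min_folds=config.min_folds,
        max_folds=config.max_folds,
        random_state=config.seed,
    )
    decision = np.zeros(len(matrix.record_ids), dtype=bool)
    decision[ok] = combiner.cross_val_decisions(matrix.values[ok], labels[ok])
    return DecisionVector(
        record_ids=list(matrix.record_ids), decision=decision, rule="random_forest"
    )
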