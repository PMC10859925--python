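"""Predictive-model check of state separability.

If detected states are real structure, ordinary classifiers should predict
state membership from spectral features well above chance — and should fall
to chance on temporally shuffled (surrogate) data.  The protocol:

* only PSD and PSD-ratio columns are used (synchrony features are windowed
  over adjacent epochs, so train/test rows would leak into each other);
* features are filtered by information value on the *training split only*
  (IV >= 0.4 per state; union over states for the multiclass task), then
  z-scored and projected to 20 principal components, both fitted on the
  training split only;
* a stratified 40% test split is held out; hyperparameters are grid-searched
  with stratified 3-fold CV on the training split;
* model families: kernel SVM, regularized logistic regression and
  gradient-boosted trees.

Reported are multiclass accuracy / macro F1 / confusion matrix, and per
state binary balanced accuracy, ROC AUC and ROC curve points.

Epoch-level random splitting mirrors the validation protocol exactly;
temporal autocorrelation inflates absolute scores, so ``block_split=True``
offers a contiguous-block alternative (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._partition import SegmentPartition
from .features import FeatureTable
from .iv_analysis import iv_values

__all__ = [
    "IVFeatureSelector",
    "exclude_sync_features",
    "StatePredictiveValidator",
    "fit_state_classifiers",
]

DEFAULT_GRIDS = {
    "svc": (
        SVC(),
        {"model__kernel": ["linear", "rbf"], "model__C": [0.1, 1.0, 10.0]},
    ),
    "logreg": (
        LogisticRegression(max_iter=2000),
        {"model__C": [0.1, 1.0, 10.0], "model__solver": ["lbfgs"]},
    ),
    "gboost": (
        HistGradientBoostingClassifier(),
        {"model__max_iter": [100], "model__max_depth": [3, None], "model__learning_rate": [0.1]},
    ),
}


class CappedPCA(PCA):
    """PCA whose dimension is clipped to what the training data supports.

    The IV filter ahead of it can keep fewer columns than the requested
    component count, and CV folds can be smaller than it; fitting with the
    feasible maximum keeps the pipeline valid.
    """

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.n_components = min(self.n_components, X.shape[0] - 1, X.shape[1])
        return super().fit(X, y)

    def fit_transform(self, X, y=None):
        X = np.asarray(X)
        self.n_components = min(self.n_components, X.shape[0] - 1, X.shape[1])
        return super().fit_transform(X, y)


class IVFeatureSelector(BaseEstimator, TransformerMixin):
    """Keep columns whose information value reaches a threshold.

    For a multiclass target the per-class IVs are computed one-vs-rest and
    a column is kept if any class reaches the threshold (the union rule).
    Falls back to keeping every column when none qualifies, so downstream
    projection always has input.
    """

    def __init__(self, threshold: float = 0.4, n_bins: int = 10):
        self.threshold = threshold
        self.n_bins = n_bins

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        import pandas as pd

        table = FeatureTable(
            X,
            pd.DataFrame(
                {"kind": "psd", "band": None, "region": None, "threshold": np.nan},
                index=pd.Index([f"f{i}" for i in range(X.shape[1])], name="name"),
            ),
        )
        keep = np.zeros(X.shape[1], dtype=bool)
        for cls in np.unique(y):
            keep |= iv_values(table, y == cls, self.n_bins) >= self.threshold
        if not keep.any():
            keep[:] = True
        self.support_ = keep
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


def exclude_sync_features(features: FeatureTable) -> FeatureTable:
    """Restrict a table to PSD and PSD-ratio columns (the classifier scope)."""
    if features.n_features == 0:
        raise ValueError("empty feature table")
    out = features.select(kind=["psd", "psd_ratio"])
    if out.n_features == 0:
        raise ValueError("no psd / psd_ratio columns present")
    return out


@dataclass
class ClassifierReport:
    """Held-out metrics for one model family."""

    family: str
    best_params: dict
    accuracy: float
    f1_macro: float
    confusion: np.ndarray
    binary: dict[int, dict] = field(default_factory=dict)  # state -> metrics


class StatePredictiveValidator(BaseEstimator):
    """Fit state-membership classifiers and report held-out separability.

    Parameters follow the validation protocol: ``test_size=0.4`` stratified,
    ``cv=3`` stratified folds, ``iv_threshold=0.4`` fitted on the training
    split, ``n_components=20`` PCA on the training split.
    """

    def __init__(
        self,
        families: tuple[str, ...] = ("svc", "logreg", "gboost"),
        test_size: float = 0.4,
        cv: int = 3,
        iv_threshold: float = 0.4,
        n_components: int = 20,
        block_split: bool = False,
        random_state: int = 0,
    ):
        self.families = families
        self.test_size = test_size
        self.cv = cv
        self.iv_threshold = iv_threshold
        self.n_components = n_components
        self.block_split = block_split
        self.random_state = random_state

    def _pipeline(self, model) -> Pipeline:
        return Pipeline(
            [
                ("iv", IVFeatureSelector(threshold=self.iv_threshold)),
                ("scale", StandardScaler()),
                ("pca", CappedPCA(n_components=self.n_components)),
                ("model", model),
            ]
        )

    def _split(self, X, y):
        if self.block_split:
            cut = int(round(len(y) * (1 - self.test_size)))
            idx = np.arange(len(y))
            return idx[:cut], idx[cut:]
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=self.test_size, stratify=y, random_state=self.random_state
        )
        return tr, te

    def fit(self, features: FeatureTable, partition: SegmentPartition) -> "StatePredictiveValidator":
        if partition.n_states < 2:
            raise ValueError("need at least two states")
        scoped = exclude_sync_features(features)
        y = partition.labels()
        if np.min(np.bincount(y)) < self.cv:
            raise ValueError("every state needs at least as many epochs as CV folds")
        X = scoped.values
        tr, te = self._split(X, y)
        self.reports_ = {}
        for family in self.families:
            model, grid = DEFAULT_GRIDS[family]
            pipe = self._pipeline(model)
            search = GridSearchCV(
                pipe,
                grid,
                cv=StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state),
            )
            search.fit(X[tr], y[tr])
            pred = search.predict(X[te])
            report = ClassifierReport(
                family=family,
                best_params=search.best_params_,
                accuracy=float(accuracy_score(y[te], pred)),
                f1_macro=float(f1_score(y[te], pred, average="macro")),
                confusion=confusion_matrix(y[te], pred),
            )
            # per-state binary tasks
            for s in range(partition.n_states):
                yb = (y == s).astype(int)
                if yb[tr].sum() < self.cv or yb[te].sum() == 0:
                    continue
                bsearch = GridSearchCV(
                    self._pipeline(model),
                    grid,
                    cv=StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state),
                )
                bsearch.fit(X[tr], yb[tr])
                bpred = bsearch.predict(X[te])
                if hasattr(bsearch.best_estimator_, "decision_function"):
                    score = bsearch.decision_function(X[te])
                else:
                    score = bsearch.predict_proba(X[te])[:, 1]
                fpr, tpr, _ = roc_curve(yb[te], score)
                report.binary[s] = {
                    "balanced_accuracy": float(balanced_accuracy_score(yb[te], bpred)),
                    "roc_auc": float(roc_auc_score(yb[te], score)),
                    "roc_curve": (fpr, tpr),
                }
            self.reports_[family] = report
        return self

    def summary(self) -> dict:
        out = {}
        for family, rep in self.reports_.items():
            out[family] = {
                "accuracy": rep.accuracy,
                "f1_macro": rep.f1_macro,
                "best_params": rep.best_params,
                "binary": {
                    s: {k: v for k, v in m.items() if k != "roc_curve"}
                    for s, m in rep.binary.items()
                },
            }
        return out


def fit_state_classifiers(
    features: FeatureTable,
    partition: SegmentPartition,
    *,
    seed: int = 0,
    **kwargs,
) -> StatePredictiveValidator:
    """Functional wrapper over :class:`StatePredictiveValidator`."""
    return StatePredictiveValidator(random_state=seed, **kwargs).fit(features, partition)
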