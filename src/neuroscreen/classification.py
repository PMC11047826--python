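"""Per-exercise classifier ensemble for neuropathy screening.

One classifier is trained per movement exercise on that exercise's
selected features; a subject's screening output is the arithmetic mean of
the six per-exercise positive-class probabilities, thresholded (default
0.5) into the binary neuropathy call.

Feature selection is one-by-one backward elimination on two-sample t-test
p-values, followed by redundancy pruning of highly correlated pairs.
Hyperparameters come from cross-validated grid search. Supported model
kinds: support vector machine, logistic regression, decision tree.

Estimator surface: :class:`TTestCorrelationSelector` (transform-shaped)
and :class:`ExerciseEnsembleClassifier` (fit/predict-shaped); the
module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    auc as trapezoid_auc,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .cohort import NEGATIVE_LABEL, POSITIVE_LABEL, CohortDataset, split_feature_column

MODEL_KINDS = ("svm", "logistic_regression", "decision_tree")

#: Default hyperparameter grids. The SVM axis spans kernels because some
#: exercises separate linearly and others need a radial-basis or
#: polynomial boundary.
DEFAULT_GRIDS = {
    "svm": {
        "clf__estimator__kernel": ["linear", "rbf", "poly"],
        "clf__estimator__C": [0.1, 1.0, 10.0],
    },
    "logistic_regression": {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "decision_tree": {"clf__max_depth": [2, 3, 4, 5, None]},
}


def _coerce_binary(y) -> np.ndarray:
    """Labels to 0/1 with 1 = neuropathy."""
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        known = {NEGATIVE_LABEL: 0, POSITIVE_LABEL: 1}
        bad = set(y) - set(known)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {list(known)}")
        return np.array([known[v] for v in y], dtype=int)
    out = y.astype(int)
    if not set(np.unique(out)) <= {0, 1}:
        raise ValueError("numeric labels must be 0/1")
    return out


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


class TTestCorrelationSelector(SelectorMixin, BaseEstimator):
    """Backward elimination on t-test p-values plus correlation pruning.

    Phase 1 repeatedly drops the feature with the largest pooled
    two-sample t-test p-value until every retained p-value is at most
    ``p_threshold``. Phase 2 scans retained pairs with absolute Pearson
    correlation above ``corr_threshold`` and keeps the member with the
    smaller p-value, so no two near-duplicate features survive.

    Ties on p-value are broken by dropping the feature with the larger
    mean absolute correlation to the others, then by column order.
    """

    def __init__(self, p_threshold: float = 0.05, corr_threshold: float = 0.9):
        self.p_threshold = p_threshold
        self.corr_threshold = corr_threshold

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = _coerce_binary(y)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present to select features")
        names = list(X_df.columns)
        values = X_df.to_numpy(dtype=float)
        pvals = {}
        for j, name in enumerate(names):
            a, b = values[y == 1, j], values[y == 0, j]
            if np.ptp(values[:, j]) == 0:
                pvals[name] = 1.0
            else:
                pvals[name] = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        corr = pd.DataFrame(values, columns=names).corr().abs().fillna(0.0)

        retained = list(names)
        while retained and max(pvals[n] for n in retained) > self.p_threshold:
            if len(retained) == 1:
                retained = []
                break
            worst_p = max(pvals[n] for n in retained)
            ties = [n for n in retained if pvals[n] == worst_p]
            if len(ties) > 1:
                mean_r = {
                    n: corr.loc[n, [m for m in retained if m != n]].mean() for n in ties
                }
                top = max(mean_r.values())
                ties = sorted(n for n in ties if mean_r[n] == top)
            retained.remove(ties[0])
        if not retained:
            raise ValueError(
                f"no feature reaches p <= {self.p_threshold}; relax p_threshold"
            )

        # redundancy pruning: of each too-correlated pair keep the smaller p
        pruned = list(retained)
        changed = True
        while changed:
            changed = False
            for i, a in enumerate(pruned):
                for b in pruned[i + 1 :]:
                    if corr.loc[a, b] > self.corr_threshold:
                        drop = b if pvals[a] <= pvals[b] else a
                        pruned.remove(drop)
                        changed = True
                        break
                if changed:
                    break

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.pvalues_ = np.array([pvals[n] for n in names])
        self.selected_features_ = pruned
        self.support_ = np.array([n in pruned for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_features(
    dataset: CohortDataset,
    exercise: str,
    p_threshold: float = 0.05,
    corr_threshold: float = 0.9,
) -> list[str]:
    """Feature names for one exercise surviving elimination and pruning."""
    cols = dataset.exercise_columns(exercise)
    if len(cols) < 1:
        raise ValueError(f"no features found for exercise {exercise!r}")
    sel = TTestCorrelationSelector(p_threshold, corr_threshold)
    sel.fit(dataset.frame[cols], dataset.y)
    return sel.selected_features_


# ---------------------------------------------------------------------------
# per-exercise models and the ensemble
# ---------------------------------------------------------------------------


def _base_estimator(model_kind: str, seed):
    if model_kind == "svm":
        # margin classifier calibrated (Platt) into a probability
        clf = CalibratedClassifierCV(SVC(gamma="scale", random_state=seed), ensemble=False)
    elif model_kind == "logistic_regression":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
    elif model_kind == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    else:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def grid_search_model(X, y, model_kind: str, param_grid=None, seed=None, cv: int = 5):
    """Cross-validated grid search returning the refitted best pipeline."""
    y = _coerce_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[model_kind]
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    search = GridSearchCV(_base_estimator(model_kind, seed), grid, cv=splitter, n_jobs=1)
    search.fit(np.asarray(X, dtype=float), y)
    return search


def train_exercise_model(
    dataset: CohortDataset,
    exercise: str,
    model_kind: str = "svm",
    param_grid=None,
    seed=None,
    feature_names=None,
    cv: int = 5,
):
    """Grid-search one exercise's classifier on its (selected) features.

    Returns the fitted :class:`~sklearn.model_selection.GridSearchCV`,
    whose best estimator emits a positive-class probability.
    """
    cols = feature_names if feature_names is not None else dataset.exercise_columns(exercise)
    missing = [c for c in cols if c not in dataset.frame.columns]
    if missing:
        raise ValueError(f"selected features absent from the training table: {missing}")
    return grid_search_model(dataset.frame[cols], dataset.y, model_kind, param_grid, seed, cv)


def split_dataset(
    dataset: CohortDataset, train_fraction: float = 0.7, seed=None
) -> tuple[CohortDataset, CohortDataset]:
    """Label-stratified train/test partition (default 70:30).

    When the cohort mixes original and synthetic rows, stratification is
    on (label, provenance) jointly so measured subjects appear in the test
    side in proportion.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie strictly in (0, 1), got {train_fraction}")
    for label, cnt in dataset.class_counts().items():
        if cnt < 2:
            raise ValueError(f"class {label!r} has {cnt} member(s); need at least 2")
    strata = dataset.frame["label"] + "/" + dataset.frame["provenance"]
    if strata.value_counts().min() < 2:
        strata = dataset.frame["label"]
    idx_train, idx_test = train_test_split(
        np.arange(len(dataset)),
        train_size=train_fraction,
        stratify=strata,
        random_state=seed,
    )
    return dataset.subset(np.sort(idx_train)), dataset.subset(np.sort(idx_test))


class ExerciseEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Ensemble of per-exercise classifiers with mean-probability aggregation.

    ``fit`` expects a feature table whose columns are named
    ``<exercise>__<feature>``. Per exercise it runs t-test/correlation
    feature selection and a cross-validated grid search for the chosen
    model kind. The ensemble probability for a subject is the arithmetic
    mean of the per-exercise positive-class probabilities; the binary
    call applies ``threshold``.

    Fitted attributes: ``exercises_``, ``selected_features_`` (dict),
    ``models_`` (dict of fitted grid searches), ``best_params_`` (dict),
    ``classes_``.
    """

    def __init__(
        self,
        model_kind: str = "svm",
        param_grid=None,
        p_threshold: float = 0.05,
        corr_threshold: float = 0.9,
        cv: int = 5,
        threshold: float = 0.5,
        random_state=None,
    ):
        self.model_kind = model_kind
        self.param_grid = param_grid
        self.p_threshold = p_threshold
        self.corr_threshold = corr_threshold
        self.cv = cv
        self.threshold = threshold
        self.random_state = random_state

    def _exercise_groups(self, columns) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for col in columns:
            exercise, feature = split_feature_column(col)
            if not feature:
                raise ValueError(
                    f"column {col!r} is not of the form '<exercise>__<feature>'"
                )
            groups.setdefault(exercise, []).append(col)
        return groups

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with '<exercise>__<feature>' columns")
        y = _coerce_binary(y)
        groups = self._exercise_groups(X.columns)
        self.exercises_ = sorted(groups)
        self.selected_features_ = {}
        self.models_ = {}
        self.best_params_ = {}
        for exercise in self.exercises_:
            sel = TTestCorrelationSelector(self.p_threshold, self.corr_threshold)
            sel.fit(X[groups[exercise]], y)
            chosen = sel.selected_features_
            search = grid_search_model(
                X[chosen], y, self.model_kind, self.param_grid, self.random_state, self.cv
            )
            self.selected_features_[exercise] = chosen
            self.models_[exercise] = search
            self.best_params_[exercise] = search.best_params_
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def exercise_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        """Positive-class probability per exercise model (columns = exercises)."""
        check_is_fitted(self, "models_")
        out = {}
        for exercise in self.exercises_:
            cols = self.selected_features_[exercise]
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"exercise {exercise!r} is missing feature(s) {missing}")
            proba = self.models_[exercise].predict_proba(X[cols].to_numpy(dtype=float))
            out[exercise] = proba[:, 1]
        return pd.DataFrame(out, index=X.index)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        per_exercise = self.exercise_probabilities(X)
        pos = aggregate_outputs(per_exercise.to_numpy())
        return np.column_stack([1 - pos, pos])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def screen(self, X: pd.DataFrame, subject_ids=None) -> list["ScreeningResult"]:
        """Per-subject screening: exercise outputs, aggregate, binary call."""
        per_exercise = self.exercise_probabilities(X)
        ids = list(subject_ids) if subject_ids is not None else [str(i) for i in X.index]
        results = []
        for i, (_, row) in enumerate(per_exercise.iterrows()):
            agg = float(row.mean())
            results.append(
                ScreeningResult(
                    subject_id=ids[i],
                    per_exercise={k: float(v) for k, v in row.items()},
                    aggregated=agg,
                    call=POSITIVE_LABEL if agg >= self.threshold else NEGATIVE_LABEL,
                )
            )
        return results


def aggregate_outputs(outputs) -> np.ndarray:
    """Arithmetic mean of per-exercise model outputs.

    ``outputs`` is (n_subjects, n_exercises) or a 1-D vector for one
    subject. Every output must lie in [0, 1]; NaN (missing exercise) is a
    hard error — no silent renormalization.
    """
    arr = np.asarray(outputs, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing exercise output; the aggregate needs all models")
    if arr.size == 0:
        raise ValueError("no exercise outputs to aggregate")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("exercise outputs must be probabilities in [0, 1]")
    return arr.mean(axis=-1)


@dataclass
class ScreeningResult:
    """One subject's screening outcome."""

    subject_id: str
    per_exercise: dict[str, float]
    aggregated: float
    call: str

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "per_exercise": self.per_exercise,
            "aggregated": self.aggregated,
            "call": self.call,
        }


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Confusion-matrix metrics plus the ROC of the aggregated score.

    Sensitivity is the recall of the neuropathy class; specificity the
    recall of the non-neuropathy class.
    """

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    sensitivity: float
    specificity: float
    accuracy: float
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    roc_thresholds: np.ndarray | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }
        if self.roc_fpr is not None:
            out["roc"] = {
                "fpr": list(map(float, self.roc_fpr)),
                "tpr": list(map(float, self.roc_tpr)),
                "thresholds": list(map(float, self.roc_thresholds)),
            }
        return out


def evaluate(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Score aggregated probabilities against the true labels.

    ``scores`` are positive-class probabilities; the binary call applies
    ``threshold``. With a single-class truth vector the ROC/AUC fields are
    left empty (a partial report) since the curve is undefined.
    """
    y_true = _coerce_binary(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("predictions and truth are not aligned")
    y_pred = (scores >= threshold).astype(int)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    label_names = (NEGATIVE_LABEL, POSITIVE_LABEL)
    report = MetricsReport(
        precision=dict(zip(label_names, map(float, prec))),
        recall=dict(zip(label_names, map(float, rec))),
        f1=dict(zip(label_names, map(float, f1))),
        support=dict(zip(label_names, map(int, support))),
        sensitivity=float(rec[1]),
        specificity=float(rec[0]),
        accuracy=float(np.mean(y_pred == y_true)),
    )
    if len(np.unique(y_true)) == 2:
        fpr, tpr, thr = roc_curve(y_true, scores)
        report.roc_fpr, report.roc_tpr, report.roc_thresholds = fpr, tpr, thr
        report.auc = float(trapezoid_auc(fpr, tpr))
    return report
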