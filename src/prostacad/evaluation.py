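"""Cross-validated classification of feature tables.

Four classical families — SVM (linear / gaussian / degree-2 polynomial
kernels), random forest (30 learning cycles), Gini decision tree, and
linear / diagonal-linear discriminant analysis — are evaluated under
stratified 5-fold, 10-fold and leave-one-out cross-validation.  Inside each
training split a grid search (inner 5-fold, accuracy criterion) picks the
hyperparameters, so test folds never inform model selection; feature
standardization lives inside the estimator pipeline for the same reason.
Each experiment is repeated (10 times by default, folds re-randomized) and
accuracy, sensitivity, specificity and AUC are reported as mean +- sd over
repeats, with sensitivity the malignant-detection rate (malignant is the
positive class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "DiagonalLDA",
    "grid_search",
    "cross_validate",
    "roc_curve",
    "metrics_from_confusion",
]

SCHEMAS = {"5fold": 5, "10fold": 10, "loo": None}

#: families whose fitted model is a deterministic function of the training data
DETERMINISTIC_FAMILIES = {"svm", "dt", "lda"}


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant with a diagonal pooled covariance.

    Class means with a shared per-feature variance — the 'diagonal linear'
    discriminant variant.  Binary decision score is the log posterior-odds
    of the positive class.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("DiagonalLDA supports binary problems only")
        n = len(y)
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        within = sum(
            ((X[y == c] - m) ** 2).sum(axis=0) for c, m in zip(self.classes_, self.means_)
        )
        self.var_ = np.maximum(within / max(n - 2, 1), 1e-12)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        m0, m1 = self.means_
        self.coef_ = (m1 - m0) / self.var_
        self.intercept_ = float(
            -0.5 * ((m1**2 - m0**2) / self.var_).sum()
            + np.log(self.priors_[1] / self.priors_[0])
        )
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def _svm_grid() -> list[dict]:
    cs = [0.1, 1.0, 10.0]
    gammas = ["scale", 0.1, 1.0]
    grid: list[dict] = [{"kernel": "linear", "C": c} for c in cs]
    grid += [{"kernel": "rbf", "C": c, "gamma": g} for c in cs for g in gammas]
    grid += [{"kernel": "poly", "C": c, "gamma": g} for c in cs for g in gammas]
    return grid


def _default_grid(family: str) -> list[dict]:
    if family == "svm":
        return _svm_grid()
    if family == "rf":
        return [{"n_estimators": 30}]
    if family == "dt":
        return [{"max_splits": s} for s in (1, 4, 10)]
    if family == "lda":
        return [{"type": "linear"}, {"type": "diag"}]
    raise ValueError(f"unknown classifier family {family!r}")


#: per-feature-set configurations reproducing the reference study's grid-search
#: winners (SVM kernel, tree split budget, discriminant type)
_FS_SVM_KERNEL = {
    "fs1": "linear", "fs2": "rbf", "fs4": "rbf", "fs6": "rbf",
    "fs3": "poly", "fs5": "poly", "fs7": "poly",
}
_FS_DT_SPLITS = {
    "fs1": 10, "fs5": 10, "fs6": 10, "fs7": 10, "fs2": 1, "fs4": 1, "fs3": 4,
}
_FS_LDA_TYPE = {"fs1": "diag", "fs2": "diag"}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter lattice.

    ``grid`` is an ordered list of parameter dicts; grid-search ties break
    toward the first point in declaration order.  ``factory``, when given,
    builds the core estimator from a parameter dict (used for custom or
    reference classifiers); otherwise the family name selects the standard
    construction.
    """

    family: str
    grid: tuple[dict, ...] = ()
    factory: Callable[..., BaseEstimator] | None = None

    def __post_init__(self) -> None:
        if not self.grid:
            object.__setattr__(self, "grid", tuple(_default_grid(self.family)))
        if len(self.grid) == 0:
            raise ValueError("hyperparameter grid must be nonempty")

    @staticmethod
    def for_feature_set(family: str, feature_set: str) -> "ClassifierSpec":
        """Narrow the lattice to the reference configuration for a feature set."""
        fs = feature_set.lower()
        if family == "svm":
            kernel = _FS_SVM_KERNEL.get(fs)
            grid = [g for g in _svm_grid() if kernel is None or g["kernel"] == kernel]
            return ClassifierSpec("svm", tuple(grid))
        if family == "dt":
            splits = _FS_DT_SPLITS.get(fs)
            grid = _default_grid("dt") if splits is None else [{"max_splits": splits}]
            return ClassifierSpec("dt", tuple(grid))
        if family == "lda":
            return ClassifierSpec("lda", ({"type": _FS_LDA_TYPE.get(fs, "linear")},))
        return ClassifierSpec(family)


def build_estimator(spec: ClassifierSpec, params: dict, seed: int = 0) -> Pipeline:
    """Scaler + classifier pipeline for one lattice point.

    Standardization sits inside the pipeline so cross-validation fits it on
    training folds only.
    """
    if spec.factory is not None:
        clf = spec.factory(**params)
    elif spec.family == "svm":
        kw = dict(params)
        if kw.get("kernel") == "poly":
            kw.setdefault("degree", 2)
        clf = SVC(**kw)
    elif spec.family == "rf":
        clf = RandomForestClassifier(random_state=seed, **params)
    elif spec.family == "dt":
        kw = dict(params)
        splits = kw.pop("max_splits", None)
        if splits is not None:
            kw["max_leaf_nodes"] = splits + 1
        clf = DecisionTreeClassifier(criterion="gini", random_state=0, **kw)
    elif spec.family == "lda":
        kw = dict(params)
        kind = kw.pop("type", "linear")
        clf = DiagonalLDA() if kind == "diag" else LinearDiscriminantAnalysis(**kw)
    else:
        raise ValueError(f"unknown classifier family {spec.family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def grid_search(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    inner_folds: int = 5,
) -> tuple[Pipeline, dict, float]:
    """Pick the lattice point maximizing inner-CV accuracy; refit on all data.

    A singleton lattice skips the inner CV entirely.  Ties go to the first
    lattice point in declaration order.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if len(spec.grid) == 1:
        params = spec.grid[0]
        est = build_estimator(spec, params, seed).fit(X, y)
        return est, dict(params), float("nan")
    k = min(inner_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=max(k, 2), shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_acc, best_params = -np.inf, None
    for params in spec.grid:
        accs = []
        for tr, te in folds:
            est = build_estimator(spec, params, seed).fit(X[tr], y[tr])
            accs.append(float((est.predict(X[te]) == y[te]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: first lattice point wins ties
            best_acc, best_params = acc, params
    est = build_estimator(spec, best_params, seed).fit(X, y)
    return est, dict(best_params), best_acc


def decision_scores(est, X: np.ndarray) -> np.ndarray:
    clf = est[-1] if isinstance(est, Pipeline) else est
    if hasattr(clf, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """(FPR, TPR) points from (0,0) to (1,1) and the trapezoidal AUC.

    Tied scores step simultaneously (one vertex per unique threshold).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy / sensitivity / specificity in percent from pooled counts."""
    total = tp + tn + fp + fn
    return {
        "accuracy": 100.0 * (tp + tn) / total if total else np.nan,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
    }


@dataclass
class EvaluationReport:
    """Per-repeat pooled metrics for one classifier x schema combination."""

    family: str
    schema: str
    repeats: int
    accuracy: np.ndarray  # percent, one entry per repeat
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray
    confusions: list[tuple[int, int, int, int]]  # (tp, tn, fp, fn) per repeat
    roc_points: np.ndarray  # pooled curve of the first repeat
    chosen_params: list[list[dict]]  # per repeat, per fold

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(arr.mean()), float(arr.std()))
            for name, arr in [
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("auc", self.auc),
            ]
        }

    def __str__(self) -> str:
        s = self.summary()
        return (
            f"{self.family}/{self.schema}: "
            f"acc {s['accuracy'][0]:.2f}±{s['accuracy'][1]:.2f}%  "
            f"sens {s['sensitivity'][0]:.2f}±{s['sensitivity'][1]:.2f}%  "
            f"spec {s['specificity'][0]:.2f}±{s['specificity'][1]:.2f}%  "
            f"auc {s['auc'][0]:.4f}±{s['auc'][1]:.4f}"
        )


def _splits(schema: str, X, y, rng_seed: int) -> Iterable[tuple[np.ndarray, np.ndarray]]:
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    k = SCHEMAS[schema]
    if k is None:
        return LeaveOneOut().split(X)
    if int(np.bincount(y).min()) < k:
        raise ValueError(
            f"{schema} needs at least {k} cases per class "
            f"(smallest class has {int(np.bincount(y).min())})"
        )
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed).split(X, y)


def cross_validate(
    table: FeatureTable,
    spec: ClassifierSpec,
    schema: str = "5fold",
    repeats: int = 10,
    seed: int = 0,
    stepwise_threshold: float | None = None,
) -> EvaluationReport:
    """Repeated stratified CV with nested grid search.

    Held-out predictions are pooled per repeat into one confusion matrix and
    one score vector (so a fold that happens to hold a single class is
    benign), then metrics are averaged across repeats.  The leave-one-out
    partition is fixed, so for deterministic families it is evaluated once
    and its sd over repeats is exactly 0.  ``stepwise_threshold`` enables the
    leakage-safe strict mode where feature selection is re-run inside every
    training fold.
    """
    X, y = table.matrix, table.labels
    if np.unique(y).size < 2:
        raise ValueError("cohort must contain both classes")
    loo_deterministic = schema == "loo" and spec.family in DETERMINISTIC_FAMILIES
    n_runs = 1 if loo_deterministic else repeats

    acc, sens, spcf, aucs = [], [], [], []
    confusions, params_all = [], []
    roc_points = None
    for r in range(n_runs):
        rng_seed = (seed * 1009 + r) % (2**31 - 1)
        preds = np.empty_like(y)
        scores = np.empty(len(y), dtype=float)
        fold_params: list[dict] = []
        for train, test in _splits(schema, X, y, rng_seed):
            cols = slice(None)
            if stepwise_threshold is not None:
                from .selection import stepwise_select

                sub = FeatureTable(
                    [table.case_ids[i] for i in train],
                    list(table.feature_names),
                    X[train],
                    y[train],
                    list(table.provenance),
                )
                chosen = stepwise_select(sub, stepwise_threshold).selected_names
                cols = [table.feature_names.index(n) for n in chosen] or [0]
            est, params, _ = grid_search(spec, X[train][:, cols], y[train], seed=rng_seed)
            preds[test] = est.predict(X[test][:, cols])
            scores[test] = decision_scores(est, X[test][:, cols])
            fold_params.append(params)
        tp = int(((preds == 1) & (y == 1)).sum())
        tn = int(((preds == 0) & (y == 0)).sum())
        fp = int(((preds == 1) & (y == 0)).sum())
        fn = int(((preds == 0) & (y == 1)).sum())
        m = metrics_from_confusion(tp, tn, fp, fn)
        points, auc = roc_curve(scores, y)
        if roc_points is None:
            roc_points = points
        acc.append(m["accuracy"])
        sens.append(m["sensitivity"])
        spcf.append(m["specificity"])
        aucs.append(auc)
        confusions.append((tp, tn, fp, fn))
        params_all.append(fold_params)

    if loo_deterministic and repeats > 1:
        acc, sens, spcf, aucs = (
            lst * repeats for lst in (acc, sens, spcf, aucs)
        )
        confusions = confusions * repeats
        params_all = params_all * repeats
    return EvaluationReport(
        family=spec.family,
        schema=schema,
        repeats=repeats,
        accuracy=np.asarray(acc),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spcf),
        auc=np.asarray(aucs),
        confusions=confusions,
        roc_points=roc_points,
        chosen_params=params_all,
    )
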