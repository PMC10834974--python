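"""Five-classifier diagnostic stage and consensus feature selection.

The protocol: stratified k-fold cross-validation (default k=5); within each
training fold an exhaustive grid search (inner 3-fold CV, ROC-AUC scoring)
picks hyperparameters, the tuned model is refitted on the training fold, and
its predictions on the held-out fold are pooled.  Pooled out-of-fold
predictions over the whole cohort give a single confusion matrix per
algorithm (decision threshold 0.5 on the positive-class score) plus a
cross-validated ROC curve and AUC.

Linear models (logistic regression, linear SVM) see z-scored features —
scaling is fitted inside each training fold; tree ensembles take raw
features.  Feature sets per model come from |standardized coefficient| for
the linear families and impurity importance for the tree families, on a
final tuned full-data refit.  The consensus panel keeps features ranked
highly by a majority of models that also pass the univariate significance
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import metrics as M
from .screen import UnivariateResult
from .simulate import CASE, metabolite_columns

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "logistic_regression",
    "svm_linear",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
)

DEFAULT_TOP_K = 15
INNER_CV_FOLDS = 3


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameter_grid: dict[str, tuple]
    cv_folds: int = 5
    scoring: str = "roc_auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ModelEvaluation:
    spec: ModelSpec
    best_hyperparameters: dict
    cm: M.ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    recall: float
    auc_roc: float
    roc_points: np.ndarray            # (n, 2) array of (fpr, tpr)
    feature_set: list[tuple[str, float]] = field(default_factory=list)

    def metrics_row(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "tp": self.cm.tp, "fp": self.cm.fp, "fn": self.cm.fn, "tn": self.cm.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "f1": self.f1, "recall": self.recall,
            "auc_roc": self.auc_roc,
        }


def default_model_specs(seed: int = 0, cv_folds: int = 5) -> dict[str, ModelSpec]:
    """Modest grids (each well under 48 combinations) for the five families."""
    grids = {
        "logistic_regression": {"clf__C": (0.01, 0.1, 1.0, 10.0)},
        "svm_linear": {"clf__C": (0.01, 0.1, 1.0, 10.0)},
        "decision_tree": {
            "clf__max_depth": (3, 5, None),
            "clf__min_samples_leaf": (1, 5),
        },
        "random_forest": {
            "clf__n_estimators": (200,),
            "clf__max_depth": (None, 5),
            "clf__max_features": ("sqrt", 0.3),
        },
        "gradient_boosting": {
            "clf__n_estimators": (100,),
            "clf__learning_rate": (0.05, 0.1),
            "clf__max_depth": (2, 3),
        },
    }
    return {
        name: ModelSpec(name, grids[name], cv_folds=cv_folds, seed=seed)
        for name in ALGORITHMS
    }


def build_estimator(algorithm: str, seed: int) -> Pipeline:
    """Untuned pipeline for one algorithm (scaler only for the linear families)."""
    if algorithm == "logistic_regression":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
    elif algorithm == "svm_linear":
        clf = SVC(kernel="linear", random_state=seed)
    elif algorithm == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif algorithm == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    elif algorithm == "gradient_boosting":
        clf = GradientBoostingClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    steps = []
    if algorithm in ("logistic_regression", "svm_linear"):
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def features_and_labels(
    table: pd.DataFrame, positive_label: str = CASE
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Numeric design matrix, boolean labels and feature names from a table.

    Rows containing NaN features (e.g. undefined ratios) are dropped with a
    log message.
    """
    names = metabolite_columns(table)
    X = table[names].to_numpy(dtype=float)
    y = (table["group"] == positive_label).to_numpy()
    ok = ~np.isnan(X).any(axis=1)
    if not ok.all():
        logger.info("dropping %d subject(s) with undefined features", int((~ok).sum()))
    return X[ok], y[ok], names


def make_folds(
    y: np.ndarray, cv_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified train/test partitions."""
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) has fewer members than folds ({cv_folds})"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def tune_and_fit(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray
) -> tuple[Pipeline, dict]:
    """Exhaustive grid search (inner CV) then refit on the full training data."""
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are degenerate (single class)")
    gs = GridSearchCV(
        build_estimator(spec.algorithm, spec.seed),
        param_grid={k: list(v) for k, v in spec.hyperparameter_grid.items()},
        scoring=spec.scoring,
        cv=StratifiedKFold(INNER_CV_FOLDS, shuffle=True, random_state=spec.seed),
        n_jobs=1,
    )
    gs.fit(X, y)
    return gs.best_estimator_, dict(gs.best_params_)


def positive_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score (probability where available)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate_predictions(
    spec: ModelSpec,
    best_params: dict,
    y_true: np.ndarray,
    scores: np.ndarray,
    pred: np.ndarray | None = None,
    threshold: float = 0.5,
) -> ModelEvaluation:
    """Metrics, confusion matrix and ROC from pooled out-of-fold predictions.

    ``pred`` carries the hard calls at the model's native 0.5
    probability / zero-margin threshold; when omitted it is derived from
    ``scores`` at ``threshold``.
    """
    y_true = np.asarray(y_true).astype(bool)
    pred = np.asarray(scores) >= threshold if pred is None else np.asarray(pred).astype(bool)
    cm = M.ConfusionMatrix(
        tp=int((pred & y_true).sum()),
        fp=int((pred & ~y_true).sum()),
        fn=int((~pred & y_true).sum()),
        tn=int((~pred & ~y_true).sum()),
    )
    if len(np.unique(y_true)) < 2:
        auc, fpr, tpr = float("nan"), np.array([0.0, 1.0]), np.array([0.0, 1.0])
        logger.warning("single-class evaluation set; AUC undefined")
    else:
        auc = M.auc_from_scores(scores, y_true)
        fpr, tpr, _ = roc_curve(y_true, scores)
    roc_points = np.column_stack([fpr, tpr])
    return ModelEvaluation(
        spec=spec,
        best_hyperparameters=best_params,
        cm=cm,
        sensitivity=M.sensitivity(cm),
        specificity=M.specificity(cm),
        accuracy=M.accuracy(cm),
        f1=M.f1(cm),
        recall=M.recall(cm),
        auc_roc=auc,
        roc_points=roc_points,
    )


def cross_validated_evaluation(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, tune: bool = True
) -> tuple[ModelEvaluation, np.ndarray]:
    """Outer-CV protocol: tune per fold, pool held-out scores, evaluate once.

    Returns the evaluation plus the pooled out-of-fold score vector.
    ``best_hyperparameters`` reports a full-data tuning pass (also used for
    the feature-set refit) when ``tune`` is on.
    """
    folds = make_folds(y, spec.cv_folds, spec.seed)
    scores = np.empty(len(y))
    pred = np.empty(len(y), dtype=bool)
    for train_idx, test_idx in folds:
        if tune:
            model, _ = tune_and_fit(spec, X[train_idx], y[train_idx])
        else:
            model = build_estimator(spec.algorithm, spec.seed).fit(X[train_idx], y[train_idx])
        scores[test_idx] = positive_scores(model, X[test_idx])
        pred[test_idx] = model.predict(X[test_idx]).astype(bool)
    if tune:
        final_model, best = tune_and_fit(spec, X, y)
    else:
        final_model, best = build_estimator(spec.algorithm, spec.seed).fit(X, y), {}
    ev = evaluate_predictions(spec, best, y, scores, pred=pred)
    ev.feature_set = model_feature_set(final_model, feature_names=None)
    return ev, scores


def model_feature_set(
    model: Pipeline,
    feature_names: list[str] | None,
    top_k: int = DEFAULT_TOP_K,
) -> list[tuple[str, float]]:
    """Ranked (feature, importance) pairs from a fitted pipeline.

    Linear families are ranked by |coefficient| on the standardized scale;
    tree families by impurity importance.  ``feature_names=None`` defers
    naming (indices are used) so callers can attach names later.
    """
    clf = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    if hasattr(clf, "coef_"):
        imp = np.abs(np.ravel(clf.coef_))
    elif hasattr(clf, "feature_importances_"):
        imp = np.asarray(clf.feature_importances_)
    else:
        raise ValueError(f"cannot rank features for {type(clf).__name__}")
    names = feature_names if feature_names is not None else [str(i) for i in range(len(imp))]
    order = np.argsort(imp)[::-1][: max(top_k, 0)]
    return [(names[i], float(imp[i])) for i in order]


def consensus_panel(
    feature_sets: dict[str, list[tuple[str, float]]],
    univariate_results: list[UnivariateResult],
    min_models: int = 3,
) -> list[dict]:
    """Features ranked highly by >= ``min_models`` classifiers AND univariately
    significant.

    Output rows carry the feature name, number of supporting models and the
    univariate AUC, ordered by support then AUC (both descending).
    """
    if len(feature_sets) < 2:
        raise ValueError("need feature sets from at least 2 models")
    passing = {r.metabolite: r for r in univariate_results if r.passes_filter}
    support: dict[str, int] = {}
    for ranked in feature_sets.values():
        for name, _ in ranked:
            support[name] = support.get(name, 0) + 1
    rows = [
        {"feature": name, "n_models": cnt, "auc": passing[name].auc,
         "p_value": passing[name].p_value}
        for name, cnt in support.items()
        if cnt >= min_models and name in passing
    ]
    rows.sort(key=lambda r: (-r["n_models"], -r["auc"]))
    return rows


def run_all(
    table: pd.DataFrame,
    univariate_results: list[UnivariateResult],
    specs: dict[str, ModelSpec] | None = None,
    seed: int = 0,
    positive_label: str = CASE,
    top_k: int = DEFAULT_TOP_K,
    min_models: int = 3,
    tune: bool = True,
) -> dict:
    """Train/evaluate all five families and derive the consensus panel.

    Returns ``{"evaluations": {algorithm: ModelEvaluation},
    "consensus_panel": [...], "scores": {algorithm: pooled scores}}``;
    deterministic given ``seed``.
    """
    specs = specs or default_model_specs(seed=seed)
    X, y, names = features_and_labels(table, positive_label)
    evaluations, all_scores, feature_sets = {}, {}, {}
    for alg, spec in specs.items():
        spec = ModelSpec(spec.algorithm, spec.hyperparameter_grid,
                         spec.cv_folds, spec.scoring, seed)
        ev, scores = cross_validated_evaluation(spec, X, y, tune=tune)
        ev.feature_set = [(names[int(i)], v) for i, v in ev.feature_set][:top_k]
        evaluations[alg] = ev
        all_scores[alg] = scores
        feature_sets[alg] = ev.feature_set
    panel = consensus_panel(feature_sets, univariate_results, min_models=min_models)
    return {"evaluations": evaluations, "consensus_panel": panel, "scores": all_scores}


__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "ModelEvaluation",
    "default_model_specs",
    "build_estimator",
    "features_and_labels",
    "make_folds",
    "tune_and_fit",
    "positive_scores",
    "evaluate_predictions",
    "cross_validated_evaluation",
    "model_feature_set",
    "consensus_panel",
    "run_all",
]
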