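"""Classifier zoo and stratified cross-validated model selection.

Twelve base learners — four SVM kernels, Gaussian naive Bayes, k-nearest
neighbours, L1/L2 logistic regression, gini/entropy decision trees and
gini/entropy extremely randomized forests — are compared under a shared
stratified 5-fold split, so leaderboards are paired comparisons. Metrics
(accuracy, F1, precision, recall; positive class = suicidal) are pooled over
the concatenated out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .corpus import ValidationError
from .features.base import FeatureBlock
from .selection import CombinationRecipe, TreeImportanceSelector

__all__ = [
    "ModelSpec",
    "CVResult",
    "default_zoo",
    "metrics_from_counts",
    "make_folds",
    "recipe_fold_columns",
    "evaluate_cv",
    "evaluate_recipe_zoo",
    "select_best",
]

ZOO_IDS = (
    "SVM-l", "SVM-rbf", "SVM-poly", "SVM-sig",
    "NB", "KNN", "Log-l1", "Log-l2",
    "DT-g", "DT-e", "ET-g", "ET-e",
)


@dataclass(frozen=True)
class ModelSpec:
    """One zoo member: an id from :data:`ZOO_IDS` plus optional overrides.

    Library defaults are used throughout except where an id fixes a
    hyperparameter (kernel, penalty, split criterion); ``probability=True``
    builds a variant that exposes ``predict_proba`` (Platt scaling for the
    SVMs) for use as a stacking base.
    """

    id: str
    seed: int = 0
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.id not in ZOO_IDS:
            raise ValidationError(f"unknown model id {self.id!r}")

    def build(self, probability: bool = False):
        extra = dict(self.params)
        s = self.seed

        def svm(kernel):
            est = SVC(kernel=kernel, random_state=s)
            if probability:
                # cross-validated Platt scaling, the probability-capable SVC
                from sklearn.calibration import CalibratedClassifierCV

                return CalibratedClassifierCV(est, ensemble=False)
            return est

        builders = {
            "SVM-l": lambda: svm("linear"),
            "SVM-rbf": lambda: svm("rbf"),
            "SVM-poly": lambda: svm("poly"),
            "SVM-sig": lambda: svm("sigmoid"),
            "NB": lambda: GaussianNB(),
            "KNN": lambda: KNeighborsClassifier(n_neighbors=5),
            "Log-l1": lambda: LogisticRegression(solver="liblinear", l1_ratio=1.0, random_state=s),
            "Log-l2": lambda: LogisticRegression(max_iter=1000, random_state=s),
            "DT-g": lambda: DecisionTreeClassifier(criterion="gini", random_state=s),
            "DT-e": lambda: DecisionTreeClassifier(criterion="entropy", random_state=s),
            "ET-g": lambda: ExtraTreesClassifier(criterion="gini", random_state=s, n_jobs=1),
            "ET-e": lambda: ExtraTreesClassifier(criterion="entropy", random_state=s, n_jobs=1),
        }
        est = builders[self.id]()
        if extra:
            est.set_params(**extra)
        return est


def default_zoo(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(mid, seed=seed) for mid in ZOO_IDS]


@dataclass
class CVResult:
    model_id: str
    accuracy: float
    f1: float
    precision: float
    recall: float
    fold_metrics: list[dict] = field(default_factory=list)
    seed: int = 0
    feature_name: str = ""

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.f1, self.precision, self.recall):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("metrics must lie in [0, 1]")


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy/precision/recall/F1 from confusion counts (positive = 1)."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def _pooled_metrics(y_true, y_pred) -> dict[str, float]:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, pos_label=1, zero_division=0)),
    }


def make_folds(labels, folds: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignment, a function of (n, labels, seed) only —
    shared across models so comparisons are paired."""
    labels = np.asarray(labels)
    if len(labels) < folds:
        raise ValidationError(f"need at least {folds} samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros((len(labels), 1)), labels))
    for train_idx, _ in splits:
        if len(np.unique(labels[train_idx])) < 2:
            raise ValidationError(
                "degenerate fold: a training fold has one class; "
                "check stratification or change the fold seed"
            )
    return splits


def recipe_fold_columns(
    recipe: CombinationRecipe,
    blocks: Mapping[str, FeatureBlock],
    labels,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    whole_data_selection: bool = False,
) -> tuple[FeatureBlock, list[np.ndarray]]:
    """Concatenated feature matrix for a recipe plus per-fold kept columns.

    Selection (when the recipe uses it) is fit on each training fold alone,
    and computed once per fold so every zoo member sees the same columns.
    With ``whole_data_selection`` the selector is instead fit once on all rows — the
    whole-data shortcut, kept for fidelity experiments.
    """
    labels = np.asarray(labels)
    parts = [blocks[b] for b in recipe.blocks]
    combined = FeatureBlock.hstack(parts)
    widths = [p.n_features for p in parts]
    offsets = np.cumsum([0] + widths)

    if not recipe.uses_selection:
        cols = np.arange(combined.n_features)
        return combined, [cols for _ in splits]

    def select_on(rows: np.ndarray) -> np.ndarray:
        if recipe.mode == "select-then-combine":
            kept = []
            for part, off in zip(parts, offsets[:-1]):
                sel = TreeImportanceSelector.from_config(recipe.selection)
                sel.fit(part.matrix[rows], labels[rows])
                kept.append(sel.kept_idx_ + off)
            return np.concatenate(kept)
        sel = TreeImportanceSelector.from_config(recipe.selection)
        sel.fit(combined.matrix[rows], labels[rows])
        return sel.kept_idx_

    if whole_data_selection:
        cols = select_on(np.arange(len(labels)))
        return combined, [cols for _ in splits]
    return combined, [select_on(train_idx) for train_idx, _ in splits]


def _evaluate_estimator(build, X, y, splits, seed, feature_name="", model_id="",
                        fold_columns=None) -> CVResult:
    y = np.asarray(y)
    oof = np.empty(len(y), dtype=int)
    fold_metrics = []
    for f, (train_idx, test_idx) in enumerate(splits):
        cols = fold_columns[f] if fold_columns is not None else slice(None)
        est = build()
        est.fit(X[np.ix_(train_idx, np.atleast_1d(cols))] if fold_columns is not None
                else X[train_idx], y[train_idx])
        pred = est.predict(X[np.ix_(test_idx, np.atleast_1d(cols))] if fold_columns is not None
                           else X[test_idx])
        oof[test_idx] = pred
        fold_metrics.append(_pooled_metrics(y[test_idx], pred))
    pooled = _pooled_metrics(y, oof)
    return CVResult(model_id=model_id, fold_metrics=fold_metrics, seed=seed,
                    feature_name=feature_name, **pooled)


def evaluate_cv(features: FeatureBlock | np.ndarray, labels, spec: ModelSpec,
                folds: int = 5, seed: int = 0, feature_name: str = "") -> CVResult:
    """Stratified k-fold evaluation of one model on one feature matrix."""
    X = features.matrix if isinstance(features, FeatureBlock) else np.asarray(features, float)
    splits = make_folds(labels, folds, seed)
    return _evaluate_estimator(lambda: spec.build(), X, labels, splits, seed,
                               feature_name=feature_name, model_id=spec.id)


def evaluate_recipe_zoo(
    recipe: CombinationRecipe,
    blocks: Mapping[str, FeatureBlock],
    labels,
    zoo: Sequence[ModelSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    whole_data_selection: bool = False,
) -> list[CVResult]:
    """Leaderboard of the zoo on one combination recipe (fold-safe selection)."""
    zoo = zoo if zoo is not None else default_zoo(seed)
    splits = make_folds(labels, folds, seed)
    combined, fold_cols = recipe_fold_columns(recipe, blocks, labels, splits, whole_data_selection)
    results = []
    for spec in zoo:
        results.append(
            _evaluate_estimator(lambda s=spec: s.build(), combined.matrix, labels, splits,
                                seed, feature_name=recipe.name, model_id=spec.id,
                                fold_columns=fold_cols)
        )
    return results


def select_best(
    features_or_results,
    labels=None,
    zoo: Sequence[ModelSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_name: str = "",
) -> tuple[ModelSpec, CVResult]:
    """Best zoo member by pooled accuracy; ties broken by F1, then zoo order.

    Accepts either a FeatureBlock + labels (runs the CV itself) or a
    pre-computed list of :class:`CVResult` aligned with ``zoo``.
    """
    if isinstance(features_or_results, (FeatureBlock, np.ndarray)):
        zoo = zoo if zoo is not None else default_zoo(seed)
        results = [
            evaluate_cv(features_or_results, labels, spec, folds, seed, feature_name)
            for spec in zoo
        ]
    else:
        results = list(features_or_results)
        if zoo is None or len(zoo) != len(results):
            raise ValidationError("select_best needs a zoo aligned with the results")
    best_i = max(range(len(results)),
                 key=lambda i: (results[i].accuracy, results[i].f1, -i))
    return zoo[best_i], results[best_i]
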