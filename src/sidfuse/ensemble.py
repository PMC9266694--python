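"""Feature-fusion stacking ensemble.

Each feature set of an :class:`EnsembleSpec` is one combination recipe over
the three feature families; together the sets must cover all of BSC, RFS and
WEC, so no base classifier's view omits a family entirely. Each set gets its
own best base classifier (chosen by cross-validated accuracy from the zoo),
whose out-of-fold positive-class probabilities become one column of the
meta-feature matrix. A logistic-regression meta-classifier is trained on
those out-of-fold columns — every meta-feature entry is produced by a model
that never saw that row in training — and the base models are then refit on
the full training data for deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .corpus import ValidationError
from .features.base import FAMILIES, FeatureBlock
from .selection import CombinationRecipe, SelectionConfig, parse_recipe
from .zoo import (
    CVResult,
    ModelSpec,
    default_zoo,
    make_folds,
    recipe_fold_columns,
    select_best,
)

__all__ = [
    "EnsembleSpec",
    "split_blocks",
    "build_meta_features",
    "choose_base_models",
    "FusionEnsembleClassifier",
    "enumerate_studied_feature_sets",
    "STUDIED_FEATURE_SETS",
]

#: The 11 studied feature-set configurations: each two-family combination in
#: each mixing regime paired with the left-out family (same regime), plus the
#: two all-single-family configurations.
STUDIED_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("BSC+RFS", "WEC"),
    ("(BSC-fs)+(RFS-fs)", "WEC-fs"),
    ("(BSC+RFS)-fs", "WEC-fs"),
    ("BSC+WEC", "RFS"),
    ("(BSC-fs)+(WEC-fs)", "RFS-fs"),
    ("(BSC+WEC)-fs", "RFS-fs"),
    ("RFS+WEC", "BSC"),
    ("(RFS-fs)+(WEC-fs)", "BSC-fs"),
    ("(RFS+WEC)-fs", "BSC-fs"),
    ("BSC", "RFS", "WEC"),
    ("BSC-fs", "RFS-fs", "WEC-fs"),
)


@dataclass(frozen=True)
class EnsembleSpec:
    feature_sets: tuple[CombinationRecipe, ...]
    base_models: tuple[ModelSpec, ...] | None = None
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.feature_sets) < 2:
            raise ValidationError("an ensemble needs at least two feature sets")
        covered = {b for r in self.feature_sets for b in r.blocks}
        missing = set(FAMILIES) - covered
        if missing:
            raise ValidationError(f"feature sets do not cover families: {sorted(missing)}")
        if self.base_models is not None and len(self.base_models) != len(self.feature_sets):
            raise ValidationError("need one base model per feature set")

    @property
    def name(self) -> str:
        return " / ".join(r.name for r in self.feature_sets)


def split_blocks(features: FeatureBlock) -> dict[str, FeatureBlock]:
    """Split a tagged FeatureBlock into its per-family blocks."""
    out = {}
    tags = np.asarray(features.column_block)
    for fam in FAMILIES:
        idx = np.flatnonzero(tags == fam)
        if idx.size:
            out[fam] = features.take_columns(idx)
    return out


def _as_blocks(X) -> Mapping[str, FeatureBlock]:
    if isinstance(X, FeatureBlock):
        return split_blocks(X)
    return X


def choose_base_models(
    spec: EnsembleSpec,
    blocks: Mapping[str, FeatureBlock],
    labels,
    zoo: Sequence[ModelSpec] | None = None,
    whole_data_selection: bool = False,
) -> tuple[EnsembleSpec, list[list[CVResult]]]:
    """Fill in each feature set's best base classifier by zoo CV."""
    from .zoo import evaluate_recipe_zoo

    zoo = zoo if zoo is not None else default_zoo(spec.seed)
    chosen, leaderboards = [], []
    for recipe in spec.feature_sets:
        results = evaluate_recipe_zoo(recipe, blocks, labels, zoo, spec.folds,
                                      spec.seed, whole_data_selection)
        best_spec, _ = select_best(results, zoo=zoo)
        chosen.append(best_spec)
        leaderboards.append(results)
    return replace(spec, base_models=tuple(chosen)), leaderboards


def build_meta_features(
    spec: EnsembleSpec,
    blocks: Mapping[str, FeatureBlock],
    labels,
    whole_data_selection: bool = False,
    splits=None,
) -> np.ndarray:
    """Out-of-fold positive-class probabilities, one column per feature set."""
    if spec.base_models is None:
        raise ValidationError("spec has no base models; call choose_base_models first")
    blocks = _as_blocks(blocks)
    labels = np.asarray(labels)
    if splits is None:
        splits = make_folds(labels, spec.folds, spec.seed)
    meta = np.zeros((len(labels), len(spec.feature_sets)))
    for s, (recipe, model) in enumerate(zip(spec.feature_sets, spec.base_models)):
        combined, fold_cols = recipe_fold_columns(recipe, blocks, labels, splits, whole_data_selection)
        for f, (train_idx, test_idx) in enumerate(splits):
            cols = fold_cols[f]
            est = model.build(probability=True)
            est.fit(combined.matrix[np.ix_(train_idx, cols)], labels[train_idx])
            proba = est.predict_proba(combined.matrix[np.ix_(test_idx, cols)])
            pos = list(est.classes_).index(1)
            meta[test_idx, s] = proba[:, pos]
    return meta


class FusionEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Stacked ensemble over per-feature-set best base classifiers.

    Parameters
    ----------
    feature_sets : sequence of recipe strings or CombinationRecipe
        The feature sets, e.g. ``["(BSC+RFS)-fs", "WEC-fs"]``. Their family
        union must cover BSC, RFS and WEC.
    base_models : sequence of model ids or ModelSpec, optional
        Fixed base classifiers; when omitted each set's base is chosen from
        the zoo by cross-validated accuracy during ``fit``.
    folds, seed : the shared stratified-CV protocol.
    whole_data_selection : fit feature selection on all training rows instead of per
        fold (the whole-data shortcut).
    selection : SelectionConfig applied to every ``-fs`` recipe.

    ``fit`` accepts either a mapping family-name -> FeatureBlock or one
    concatenated, family-tagged FeatureBlock.
    """

    def __init__(self, feature_sets=("(BSC+RFS)-fs", "WEC-fs"), base_models=None,
                 folds: int = 5, seed: int = 0, whole_data_selection: bool = False,
                 selection: SelectionConfig | None = None):
        self.feature_sets = feature_sets
        self.base_models = base_models
        self.folds = folds
        self.seed = seed
        self.whole_data_selection = whole_data_selection
        self.selection = selection

    def _recipes(self) -> tuple[CombinationRecipe, ...]:
        selection = self.selection or SelectionConfig(seed=self.seed)
        out = []
        for fs in self.feature_sets:
            recipe = fs if isinstance(fs, CombinationRecipe) else parse_recipe(fs)
            out.append(recipe.with_selection(selection))
        return tuple(out)

    def fit(self, X, y) -> "FusionEnsembleClassifier":
        blocks = _as_blocks(X)
        y = np.asarray(y)
        spec = EnsembleSpec(self._recipes(), folds=self.folds, seed=self.seed)
        if self.base_models is not None:
            models = tuple(
                m if isinstance(m, ModelSpec) else ModelSpec(m, seed=self.seed)
                for m in self.base_models
            )
            spec = replace(spec, base_models=models)
            self.leaderboards_ = None
        else:
            spec, self.leaderboards_ = choose_base_models(
                spec, blocks, y, whole_data_selection=self.whole_data_selection
            )
        self.spec_ = spec
        self.meta_features_ = build_meta_features(spec, blocks, y, self.whole_data_selection)
        self.meta_model_ = LogisticRegression(max_iter=1000, random_state=self.seed)
        self.meta_model_.fit(self.meta_features_, y)
        # refit base models (and their selectors) on the full training data
        self.fitted_sets_ = []
        for recipe, model in zip(spec.feature_sets, spec.base_models):
            combined = FeatureBlock.hstack([blocks[b] for b in recipe.blocks])
            if recipe.uses_selection:
                splits = [(np.arange(len(y)), np.arange(len(y)))]
                _, cols = recipe_fold_columns(recipe, blocks, y, splits, whole_data_selection=True)
                cols = cols[0]
            else:
                cols = np.arange(combined.n_features)
            est = model.build(probability=True)
            est.fit(combined.matrix[:, cols], y)
            self.fitted_sets_.append((recipe, cols, est))
        self.classes_ = np.array([0, 1])
        return self

    def _meta_matrix(self, X) -> np.ndarray:
        blocks = _as_blocks(X)
        n = len(next(iter(blocks.values())).row_ids)
        meta = np.zeros((n, len(self.fitted_sets_)))
        for s, (recipe, cols, est) in enumerate(self.fitted_sets_):
            combined = FeatureBlock.hstack([blocks[b] for b in recipe.blocks])
            proba = est.predict_proba(combined.matrix[:, cols])
            pos = list(est.classes_).index(1)
            meta[:, s] = proba[:, pos]
        return meta

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "meta_model_"):
            raise ValidationError("ensemble is not fitted")
        return self.meta_model_.predict_proba(self._meta_matrix(X))

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "meta_model_"):
            raise ValidationError("ensemble is not fitted")
        return self.meta_model_.predict(self._meta_matrix(X))


def enumerate_studied_feature_sets(
    selection: SelectionConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> list[EnsembleSpec]:
    """The 11 studied feature-set configurations as ensemble specs."""
    selection = selection or SelectionConfig(seed=seed)
    specs = []
    for recipes in STUDIED_FEATURE_SETS:
        feature_sets = tuple(parse_recipe(r, selection) for r in recipes)
        specs.append(EnsembleSpec(feature_sets, folds=folds, seed=seed))
    return specs
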