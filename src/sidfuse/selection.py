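"""Extremely-randomized-trees feature selection and feature-combination
recipes.

High-dimensional sparse text features are pruned with the impurity-based
importances of an extremely randomized forest. A :class:`CombinationRecipe`
names a subset of the three feature families (BSC, RFS, WEC) and one of three
mixing regimes, written in the field's ``-fs`` notation:

* ``BSC+RFS``            — direct column concatenation,
* ``(BSC-fs)+(RFS-fs)``  — select within each family, then concatenate,
* ``(BSC+RFS)-fs``       — concatenate, then one selection over the joint
  matrix (which can keep jointly-informative columns that per-family
  selection would discard).

By default the selector is refit inside each cross-validation training fold
(no label leakage); the ``whole_data_selection`` flag reproduces the common
shortcut of selecting once on all rows before cross-validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import ExtraTreesClassifier

from .corpus import ValidationError
from .features.base import FAMILIES, FeatureBlock

__all__ = [
    "SelectionConfig",
    "TreeImportanceSelector",
    "fit_importance_selector",
    "CombinationRecipe",
    "parse_recipe",
    "apply_recipe",
]

MODES = ("direct", "select-then-combine", "combine-then-select")


@dataclass(frozen=True)
class SelectionConfig:
    n_trees: int = 500
    criterion: str = "gini"
    top_k: int | None = None
    fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in ("gini", "entropy"):
            raise ValidationError(f"criterion {self.criterion!r} not in {{gini, entropy}}")
        if self.top_k is not None and self.top_k <= 0:
            raise ValidationError("top_k must be strictly positive")
        if not (0.0 < self.fraction <= 1.0):
            raise ValidationError("fraction must lie in (0, 1]")
        if self.n_trees <= 0:
            raise ValidationError("n_trees must be positive")


class TreeImportanceSelector(BaseEstimator, TransformerMixin):
    """Keep the importance-ranked prefix of columns of a feature matrix.

    The keep rule is either a fixed ``top_k`` or the smallest prefix whose
    cumulative normalized importance reaches ``fraction`` (default 0.95).
    Accepts and returns either plain arrays or :class:`FeatureBlock`.
    """

    def __init__(self, n_trees: int = 500, criterion: str = "gini",
                 top_k: int | None = None, fraction: float = 0.95, seed: int = 0):
        self.n_trees = n_trees
        self.criterion = criterion
        self.top_k = top_k
        self.fraction = fraction
        self.seed = seed

    @classmethod
    def from_config(cls, config: SelectionConfig) -> "TreeImportanceSelector":
        return cls(n_trees=config.n_trees, criterion=config.criterion,
                   top_k=config.top_k, fraction=config.fraction, seed=config.seed)

    def fit(self, X, y) -> "TreeImportanceSelector":
        M = X.matrix if isinstance(X, FeatureBlock) else np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValidationError("feature selection needs at least two classes")
        SelectionConfig(self.n_trees, self.criterion, self.top_k, self.fraction, self.seed)
        forest = ExtraTreesClassifier(
            n_estimators=self.n_trees,
            criterion=self.criterion,
            random_state=self.seed,
            n_jobs=1,
        ).fit(M, y)
        imp = forest.feature_importances_.astype(float)
        if imp.sum() <= 0:  # all-constant features: fall back to uniform
            imp = np.full(M.shape[1], 1.0 / M.shape[1])
        imp = imp / imp.sum()
        order = np.lexsort((np.arange(len(imp)), -imp))  # stable: ties keep column order
        if self.top_k is not None:
            keep = min(self.top_k, len(imp))
        else:
            keep = int(np.searchsorted(np.cumsum(imp[order]), self.fraction - 1e-12) + 1)
            keep = min(keep, len(imp))
        self.importances_ = imp
        self.ranking_ = order
        self.kept_idx_ = np.sort(order[:keep])  # original column order preserved
        return self

    def transform(self, X):
        if isinstance(X, FeatureBlock):
            return X.take_columns(self.kept_idx_)
        return np.asarray(X, dtype=float)[:, self.kept_idx_]

    def get_support(self, indices: bool = False):
        if indices:
            return self.kept_idx_
        mask = np.zeros(len(self.importances_), dtype=bool)
        mask[self.kept_idx_] = True
        return mask


def fit_importance_selector(block: FeatureBlock, labels, config: SelectionConfig) -> TreeImportanceSelector:
    """Fit a tree-importance selector on one feature block."""
    return TreeImportanceSelector.from_config(config).fit(block, labels)


# ---------------------------------------------------------------------------
# combination recipes


@dataclass(frozen=True)
class CombinationRecipe:
    blocks: tuple[str, ...]
    mode: str = "direct"
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("recipe needs at least one feature family")
        bad = set(self.blocks) - set(FAMILIES)
        if bad:
            raise ValidationError(f"unknown feature families: {sorted(bad)}")
        if len(set(self.blocks)) != len(self.blocks):
            raise ValidationError("duplicate feature family in recipe")
        if self.mode not in MODES:
            raise ValidationError(f"mode {self.mode!r} not in {MODES}")

    @property
    def name(self) -> str:
        inner = "+".join(self.blocks)
        if self.mode == "direct":
            return inner
        if len(self.blocks) == 1:
            return f"{self.blocks[0]}-fs"
        if self.mode == "select-then-combine":
            return "+".join(f"({b}-fs)" for b in self.blocks)
        return f"({inner})-fs"

    @property
    def uses_selection(self) -> bool:
        return self.mode != "direct"

    def with_selection(self, selection: SelectionConfig) -> "CombinationRecipe":
        return replace(self, selection=selection)


def parse_recipe(text: str, selection: SelectionConfig | None = None) -> CombinationRecipe:
    """Parse a recipe string in the ``-fs`` notation.

    Accepted forms (whitespace ignored): ``BSC``, ``BSC+RFS+WEC``, ``BSC-fs``,
    ``(BSC+RFS)-fs``, ``(BSC-fs)+(WEC-fs)``.
    """
    selection = selection or SelectionConfig()
    s = re.sub(r"\s+", "", text)
    if not s:
        raise ValidationError("empty recipe string")
    m = re.fullmatch(r"\(([A-Z+]+)\)-fs", s)
    if m:
        return CombinationRecipe(tuple(m.group(1).split("+")), "combine-then-select", selection)
    if "(" in s:
        parts = s.split("+(")
        blocks = []
        for part in parts:
            m = re.fullmatch(r"\(?([A-Z]+)-fs\)?", part)
            if not m:
                raise ValidationError(f"cannot parse recipe {text!r}")
            blocks.append(m.group(1))
        return CombinationRecipe(tuple(blocks), "select-then-combine", selection)
    m = re.fullmatch(r"([A-Z]+)-fs", s)
    if m:
        return CombinationRecipe((m.group(1),), "combine-then-select", selection)
    if re.fullmatch(r"[A-Z]+(\+[A-Z]+)*", s):
        return CombinationRecipe(tuple(s.split("+")), "direct", selection)
    raise ValidationError(f"cannot parse recipe {text!r}")


def _gather(recipe: CombinationRecipe, blocks: Mapping[str, FeatureBlock]) -> list[FeatureBlock]:
    missing = [b for b in recipe.blocks if b not in blocks]
    if missing:
        raise ValidationError(f"recipe {recipe.name!r}: missing feature blocks {missing}")
    return [blocks[b] for b in recipe.blocks]


def apply_recipe(
    recipe: CombinationRecipe,
    blocks: Mapping[str, FeatureBlock],
    labels=None,
) -> FeatureBlock:
    """Materialize a recipe on full data (selection fit on all rows/labels).

    For leakage-free evaluation the selector is instead refit inside each CV
    training fold; see :func:`sidfuse.zoo.recipe_fold_columns`.
    """
    parts = _gather(recipe, blocks)
    if recipe.mode == "direct":
        return FeatureBlock.hstack(parts)
    if labels is None:
        raise ValidationError(f"recipe {recipe.name!r} requires labels for feature selection")
    if recipe.mode == "select-then-combine":
        selected = [
            TreeImportanceSelector.from_config(recipe.selection).fit(p, labels).transform(p)
            for p in parts
        ]
        return FeatureBlock.hstack(selected)
    combined = FeatureBlock.hstack(parts)
    sel = TreeImportanceSelector.from_config(recipe.selection).fit(combined, labels)
    return sel.transform(combined)
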