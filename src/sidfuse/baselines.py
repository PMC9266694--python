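"""Reference ensemble baselines and the reporting layer.

Nine configurations evaluated under the same stratified 5-fold protocol as
the fusion model: random forests (gini and entropy splits), XGBoost with tree
and linear boosters, AdaBoost and bagging over decision trees, gradient
boosting, classic stacking whose bases are the previously selected best zoo
members, and a majority-class dummy giving the prevalence floor.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.linear_model import LogisticRegression

from .corpus import ValidationError
from .features.base import FeatureBlock
from .zoo import CVResult, ModelSpec, _evaluate_estimator, make_folds

__all__ = ["BASELINE_NAMES", "run_baselines", "report"]

#: default stacking bases: the best classifiers found in the model-selection
#: stages (linear SVM, L1/L2 logistic regression, naive Bayes, both forests)
DEFAULT_STACKING_BASES = ("SVM-l", "Log-l1", "Log-l2", "NB", "ET-g", "ET-e")

BASELINE_NAMES = (
    "RF-entropy",
    "RF-gini",
    "XGB-gbtree",
    "XGB-gblinear",
    "AdaBoost-tree",
    "Bagging-tree",
    "GradientBoosting",
    "Stacking",
    "Dummy-majority",
)


def _xgb(booster: str, seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(booster=booster, random_state=seed, n_jobs=1,
                         eval_metric="logloss", verbosity=0)


def run_baselines(
    features: FeatureBlock | np.ndarray,
    labels,
    seed: int = 0,
    folds: int = 5,
    stacking_bases: Sequence[ModelSpec | str] = DEFAULT_STACKING_BASES,
) -> list[CVResult]:
    """Evaluate all baseline ensembles on one feature matrix, shared folds."""
    X = features.matrix if isinstance(features, FeatureBlock) else np.asarray(features, float)
    y = np.asarray(labels)
    splits = make_folds(y, folds, seed)
    bases = [m if isinstance(m, ModelSpec) else ModelSpec(m, seed=seed) for m in stacking_bases]

    builders = {
        "RF-entropy": lambda: RandomForestClassifier(criterion="entropy", random_state=seed, n_jobs=1),
        "RF-gini": lambda: RandomForestClassifier(criterion="gini", random_state=seed, n_jobs=1),
        "XGB-gbtree": lambda: _xgb("gbtree", seed),
        "XGB-gblinear": lambda: _xgb("gblinear", seed),
        "AdaBoost-tree": lambda: AdaBoostClassifier(random_state=seed),
        "Bagging-tree": lambda: BaggingClassifier(random_state=seed),
        "GradientBoosting": lambda: GradientBoostingClassifier(random_state=seed),
        "Stacking": lambda: StackingClassifier(
            estimators=[(m.id, m.build(probability=True)) for m in bases],
            final_estimator=LogisticRegression(max_iter=1000, random_state=seed),
            cv=folds,
            n_jobs=1,
        ),
        "Dummy-majority": lambda: DummyClassifier(strategy="most_frequent"),
    }
    return [
        _evaluate_estimator(builders[name], X, y, splits, seed, model_id=name)
        for name in BASELINE_NAMES
    ]


# ---------------------------------------------------------------------------
# reporting

_TABLE_NAMES = ("single_feature", "multi_feature", "fusion", "baselines")
_METRIC_COLS = ("accuracy", "f1", "precision", "recall")


def _format_row(row: Mapping) -> dict:
    out = {}
    for key, val in row.items():
        if key in _METRIC_COLS:
            out[key] = f"{100 * float(val):.2f}%"
        else:
            out[key] = val
    return out


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def report(tables: Mapping[str, Sequence[Mapping]], out_dir: str | Path,
           config: Mapping | None = None) -> dict[str, Path]:
    """Write the four leaderboard tables as CSV plus run metadata as JSON.

    ``tables`` maps each of ``single_feature``, ``multi_feature``, ``fusion``
    and ``baselines`` to rows (mappings); metric columns are formatted as
    percentages with two decimals. Metadata records the config and a stable
    hash of it, so identical runs produce identical files.
    """
    import pandas as pd

    missing = set(_TABLE_NAMES) - set(tables)
    if missing:
        raise ValidationError(f"report is missing tables: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in _TABLE_NAMES:
        rows = [_format_row(r) for r in tables[name]]
        path = out_dir / f"table_{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written[name] = path
    config = dict(config or {})
    meta = {
        "config": config,
        "config_hash": _config_hash(config),
        "python": platform.python_version(),
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    written["metadata"] = meta_path
    return written
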