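"""End-to-end study protocols on synthetic corpora.

Each function here runs one self-contained computational experiment on
generated data and returns plain numbers: the K-means-vs-brute-force
optimality check, the permutation leakage test on out-of-fold meta-features,
the signal-recovery study (single-feature, multi-feature and fusion
leaderboards over several generator seeds), a byte-level determinism check of
the reporting pipeline, and the structural bookkeeping counts. They are the
backbone of the acceptance checks and of the ``compare`` CLI.

Problem sizes default to desk scale (thousands of posts, not the full
40,222-post default corpus) so a study finishes in minutes on one core; the
generator's distributional defaults are untouched, only ``n_pos``/``n_neg``
are scaled.
"""

from __future__ import annotations

import filecmp
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .baselines import run_baselines, report
from .corpus import Corpus, Lexicon
from .ensemble import EnsembleSpec, build_meta_features, choose_base_models
from .features.base import FeatureBlock
from .features.bsc import bsc_block
from .features.rfs import rfs_block
from .features.wec import extract_candidates, kmeans_cluster, select_keywords, wec_block, _lloyd
from .features.embedding import SkipGramConfig, train_skipgram
from .selection import SelectionConfig, parse_recipe
from .synthetic import GeneratorConfig, generate_corpus, make_fixture_lexicons
from .zoo import (
    _pooled_metrics,
    default_zoo,
    evaluate_recipe_zoo,
    make_folds,
    select_best,
)

__all__ = [
    "brute_force_wcss",
    "kmeans_oracle_study",
    "build_feature_blocks",
    "leakage_study",
    "signal_recovery_study",
    "fusion_pooled_metrics",
    "run_reporting_pipeline",
    "determinism_study",
    "structure_fidelity_study",
    "prevalence_baseline_f1",
]

#: headline fusion configuration: joint selection over BSC+RFS, WEC selected
#: separately
HEADLINE_FEATURE_SETS = ("(BSC+RFS)-fs", "WEC-fs")


# ---------------------------------------------------------------------------
# K-means vs brute force


def brute_force_wcss(X: np.ndarray, k: int) -> float:
    """Exact minimal within-cluster sum of squares by enumerating every
    surjective assignment of the points to k clusters. Tractable only for
    tiny instances (n <= ~10)."""
    n = len(X)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        a = np.asarray(assign)
        w = 0.0
        for c in range(k):
            pts = X[a == c]
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
        if w < best:
            best = w
    return best


def kmeans_oracle_study(seed: int = 0, n_instances: int = 60) -> dict:
    """Compare Lloyd clustering with exact enumeration on tiny instances.

    Instances are k small Gaussian blobs in the plane (random centres,
    spread 0.5), n in [4, 8], k in {2, 3} — the geometry the keyword
    clustering step faces in miniature. Returns the fraction of instances
    where Lloyd's final objective equals the optimum, and whether it ever
    (impossibly) beat the optimum.
    """
    rng = np.random.default_rng(seed)
    matches = 0
    beaten = 0
    for _ in range(n_instances):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, 4))
        centers = rng.normal(0.0, 3.0, (k, 2))
        X = centers[rng.integers(k, size=n)] + rng.normal(0.0, 0.5, (n, 2))
        best = None
        for run in range(10):  # kmeans_cluster's default restart count
            assign, cent, _ = _lloyd(X, k, int(rng.integers(2**31)) , 300)
            w = float(((X - cent[assign]) ** 2).sum())
            if best is None or w < best:
                best = w
        opt = brute_force_wcss(X, k)
        if best < opt - 1e-9:
            beaten += 1
        elif best <= opt + 1e-9:
            matches += 1
    return {
        "n_instances": n_instances,
        "match_rate": matches / n_instances,
        "ever_beats_oracle": bool(beaten),
    }


# ---------------------------------------------------------------------------
# shared pipeline pieces


@dataclass
class StudyScale:
    """Problem sizes for one study run; distributional defaults untouched."""

    n_pos: int = 400
    n_neg: int = 3600
    embedding_dim: int = 50
    embedding_epochs: int = 5
    k_clusters: int = 10
    m_per_cluster: int = 10
    selection_trees: int = 500


def build_feature_blocks(
    corpus: Corpus, lexicons: Sequence[Lexicon], seed: int, scale: StudyScale
) -> dict[str, FeatureBlock]:
    """BSC, RFS and WEC blocks for one corpus (trains the embeddings)."""
    by_kind = {lex.kind: lex for lex in lexicons}
    emb = train_skipgram(
        corpus,
        SkipGramConfig(dim=scale.embedding_dim, epochs=scale.embedding_epochs, seed=seed),
    )
    cands = extract_candidates(corpus, embeddings=emb)
    clustering = kmeans_cluster(cands, emb, k=min(scale.k_clusters, len(cands)), seed=seed)
    keywords = select_keywords(clustering, scale.m_per_cluster)
    return {
        "BSC": bsc_block(corpus, [by_kind[k] for k in
                                  ("category-count", "polarity", "degree-adverb", "emoji")]),
        "RFS": rfs_block(corpus, by_kind["risk-dictionary"]),
        "WEC": wec_block(corpus, keywords, clustering),
    }


def prevalence_baseline_f1(labels) -> float:
    """F1 of the trivial everyone-positive classifier: 2p / (1 + p)."""
    p = float(np.mean(labels))
    return 2 * p / (1 + p)


def fusion_pooled_metrics(spec: EnsembleSpec, blocks, labels, seed: int) -> dict[str, float]:
    """Pooled out-of-fold metrics of the fused model: the meta-classifier is
    itself 5-fold cross-validated on the out-of-fold meta-feature matrix, so
    no base model nor meta model ever scored a row it was trained on."""
    labels = np.asarray(labels)
    meta = build_meta_features(spec, blocks, labels)
    splits = make_folds(labels, spec.folds, seed)
    oof = np.empty(len(labels), dtype=int)
    for train_idx, test_idx in splits:
        lr = LogisticRegression(max_iter=1000, random_state=seed)
        lr.fit(meta[train_idx], labels[train_idx])
        oof[test_idx] = lr.predict(meta[test_idx])
    return _pooled_metrics(labels, oof)


# ---------------------------------------------------------------------------
# leakage (permutation-null) study


def leakage_study(seed: int = 0, n_posts: int = 2000, pos_frac: float = 0.1,
                  n_permutations: int = 20) -> dict:
    """Out-of-fold meta-features under permuted labels must carry no signal.

    With labels randomly permuted, each meta-feature column's out-of-fold AUC
    should sit at 0.5; systematic deviation would indicate label leakage into
    the stacking stage. Base models are fixed to L2 logistic regression so
    the test isolates the out-of-fold discipline itself.
    """
    n_pos = int(round(n_posts * pos_frac))
    config = GeneratorConfig(seed=seed).scaled(n_pos, n_posts - n_pos)
    lexicons = make_fixture_lexicons(config)
    corpus = generate_corpus(config, lexicons)
    scale = StudyScale(embedding_epochs=3)
    blocks = build_feature_blocks(corpus, lexicons, seed, scale)
    labels = corpus.labels()

    from .zoo import ModelSpec

    spec = EnsembleSpec(
        feature_sets=(parse_recipe("BSC+RFS"), parse_recipe("WEC")),
        base_models=(ModelSpec("Log-l2", seed=seed), ModelSpec("Log-l2", seed=seed)),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    aucs = np.zeros((n_permutations, len(spec.feature_sets)))
    for p in range(n_permutations):
        permuted = rng.permutation(labels)
        meta = build_meta_features(spec, blocks, permuted)
        for s in range(meta.shape[1]):
            aucs[p, s] = roc_auc_score(permuted, meta[:, s])
    mean_auc = aucs.mean(axis=0)
    return {
        "mean_auc_per_column": mean_auc.tolist(),
        "max_abs_deviation": float(np.max(np.abs(mean_auc - 0.5))),
        "n_permutations": n_permutations,
        "n_posts": n_posts,
    }


# ---------------------------------------------------------------------------
# signal-recovery study


TWO_FAMILY_RECIPES = ("BSC+RFS", "BSC+WEC", "RFS+WEC")
THREE_FAMILY_RECIPE = "BSC+RFS+WEC"


def signal_recovery_study(seed: int = 0, n_seeds: int = 5, n_posts: int = 4000,
                          pos_frac: float = 0.1, scale: StudyScale | None = None) -> dict:
    """Full pipeline over several generator seeds at desk scale.

    Per seed: best zoo member per single feature family; best zoo member per
    direct two-family and three-family combination; pooled F1 of the headline
    fusion configuration. Returns per-seed numbers plus the three directional
    summaries: (a) RFS beats the everyone-positive prevalence baseline,
    (b) fusion F1 is within 0.01 of (or above) the best single-feature model,
    (c) the three-family combination matches or beats the two-family average.
    """
    scale = scale or StudyScale()
    n_pos = int(round(n_posts * pos_frac))
    per_seed = []
    for i in range(n_seeds):
        run_seed = seed + i
        config = GeneratorConfig(seed=run_seed).scaled(n_pos, n_posts - n_pos)
        lexicons = make_fixture_lexicons(config)
        corpus = generate_corpus(config, lexicons)
        blocks = build_feature_blocks(corpus, lexicons, run_seed, scale)
        labels = corpus.labels()
        zoo = default_zoo(seed=run_seed)
        selection = SelectionConfig(n_trees=scale.selection_trees, seed=run_seed)

        singles = {}
        for fam in ("BSC", "RFS", "WEC"):
            recipe = parse_recipe(fam)
            results = evaluate_recipe_zoo(recipe, blocks, labels, zoo, seed=run_seed)
            best, res = select_best(results, zoo=zoo)
            singles[fam] = {"model": best.id, "accuracy": res.accuracy, "f1": res.f1}

        combos = {}
        for text in (*TWO_FAMILY_RECIPES, THREE_FAMILY_RECIPE):
            recipe = parse_recipe(text, selection)
            results = evaluate_recipe_zoo(recipe, blocks, labels, zoo, seed=run_seed)
            best, res = select_best(results, zoo=zoo)
            combos[text] = {"model": best.id, "accuracy": res.accuracy, "f1": res.f1}

        spec = EnsembleSpec(
            tuple(parse_recipe(r, selection) for r in HEADLINE_FEATURE_SETS),
            seed=run_seed,
        )
        spec, _ = choose_base_models(spec, blocks, labels, zoo=zoo)
        fusion = fusion_pooled_metrics(spec, blocks, labels, run_seed)

        per_seed.append(
            {
                "seed": run_seed,
                "singles": singles,
                "combos": combos,
                "fusion": fusion,
                "fusion_bases": [m.id for m in spec.base_models],
                "baseline_f1": prevalence_baseline_f1(labels),
            }
        )

    rfs_beats = [s["singles"]["RFS"]["f1"] > s["baseline_f1"] for s in per_seed]
    fusion_holds = [
        s["fusion"]["f1"] >= max(f["f1"] for f in s["singles"].values()) - 0.01
        for s in per_seed
    ]
    two_mean = float(np.mean([
        s["combos"][r]["f1"] for s in per_seed for r in TWO_FAMILY_RECIPES
    ]))
    three_mean = float(np.mean([s["combos"][THREE_FAMILY_RECIPE]["f1"] for s in per_seed]))
    return {
        "per_seed": per_seed,
        "rfs_beats_baseline_all_seeds": all(rfs_beats),
        "fusion_at_least_best_single_count": int(sum(fusion_holds)),
        "n_seeds": n_seeds,
        "two_family_mean_f1": two_mean,
        "three_family_mean_f1": three_mean,
        "mean_fusion_f1": float(np.mean([s["fusion"]["f1"] for s in per_seed])),
        "mean_best_single_f1": float(np.mean([
            max(f["f1"] for f in s["singles"].values()) for s in per_seed
        ])),
    }


# ---------------------------------------------------------------------------
# reporting pipeline + determinism


def run_reporting_pipeline(seed: int, out_dir: str | Path, n_posts: int = 1000,
                           pos_frac: float = 0.1, scale: StudyScale | None = None) -> dict:
    """Generate a corpus, run every stage, and write the four report tables.

    Used by the ``compare`` CLI and by the determinism check: all randomness
    descends from ``seed``, so two runs with the same seed must produce
    byte-identical files.
    """
    scale = scale or StudyScale(embedding_epochs=3, selection_trees=200)
    n_pos = int(round(n_posts * pos_frac))
    config = GeneratorConfig(seed=seed).scaled(n_pos, n_posts - n_pos)
    lexicons = make_fixture_lexicons(config)
    corpus = generate_corpus(config, lexicons)
    blocks = build_feature_blocks(corpus, lexicons, seed, scale)
    labels = corpus.labels()
    zoo = default_zoo(seed=seed)
    selection = SelectionConfig(n_trees=scale.selection_trees, seed=seed)

    def leaderboard_rows(recipe_texts):
        rows = []
        for text in recipe_texts:
            recipe = parse_recipe(text, selection)
            results = evaluate_recipe_zoo(recipe, blocks, labels, zoo, seed=seed)
            best, res = select_best(results, zoo=zoo)
            rows.append({"feature": text, "accuracy": res.accuracy, "f1": res.f1,
                         "precision": res.precision, "recall": res.recall,
                         "optimum_classifier": best.id})
        return rows

    single_rows = leaderboard_rows(["BSC", "RFS", "WEC"])
    multi_rows = leaderboard_rows([*TWO_FAMILY_RECIPES, THREE_FAMILY_RECIPE])

    spec = EnsembleSpec(tuple(parse_recipe(r, selection) for r in HEADLINE_FEATURE_SETS),
                        seed=seed)
    spec, _ = choose_base_models(spec, blocks, labels, zoo=zoo)
    fusion = fusion_pooled_metrics(spec, blocks, labels, seed)
    fusion_rows = [{"feature_set": spec.name,
                    "base_models": "+".join(m.id for m in spec.base_models),
                    **fusion}]

    combined = FeatureBlock.hstack([blocks[f] for f in ("BSC", "RFS", "WEC")])
    baseline_rows = [
        {"model": r.model_id, "accuracy": r.accuracy, "f1": r.f1,
         "precision": r.precision, "recall": r.recall}
        for r in run_baselines(combined, labels, seed=seed)
    ]

    tables = {
        "single_feature": single_rows,
        "multi_feature": multi_rows,
        "fusion": fusion_rows,
        "baselines": baseline_rows,
    }
    report(tables, out_dir, config={"seed": seed, "n_posts": n_posts, "pos_frac": pos_frac})
    return tables


def determinism_study(seed: int = 0, n_posts: int = 800, pos_frac: float = 0.1,
                      work_dir: str | Path | None = None) -> dict:
    """Run the reporting pipeline twice with one seed; files must be
    byte-identical."""
    import tempfile

    base = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="sidfuse-det-"))
    dirs = [base / "run1", base / "run2"]
    for d in dirs:
        run_reporting_pipeline(seed, d, n_posts=n_posts, pos_frac=pos_frac)
    names = sorted(p.name for p in dirs[0].iterdir())
    identical = all(
        filecmp.cmp(dirs[0] / name, dirs[1] / name, shallow=False) for name in names
    )
    return {"identical": identical, "files": names, "n_posts": n_posts}


# ---------------------------------------------------------------------------
# structural bookkeeping


def structure_fidelity_study() -> dict:
    """Counts fixed by the data-set and method structure: default class split,
    number of time bins, risk-dictionary categories, studied feature-set
    configurations."""
    from .ensemble import enumerate_studied_feature_sets
    from .features.bsc import N_TIME_BINS

    config = GeneratorConfig(seed=0)
    lexicons = make_fixture_lexicons(config)
    corpus = generate_corpus(config, lexicons)
    labels = corpus.labels()
    specs = enumerate_studied_feature_sets()
    names = {tuple(r.name for r in s.feature_sets) for s in specs}
    return {
        "n_positive": int(labels.sum()),
        "n_negative": int((1 - labels).sum()),
        "n_time_bins": N_TIME_BINS,
        "n_risk_categories": len([l for l in lexicons if l.kind == "risk-dictionary"][0].categories),
        "n_feature_set_configs": len(specs),
        "headline_config_present": ("(BSC+RFS)-fs", "WEC-fs") in names,
    }
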