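"""Word-embedding clustering (WEC) features.

Pipeline: train skip-gram embeddings on the corpus; keep unique content words
(POS-filtered) that survived the embedding vocabulary cut as candidate
keywords; cluster their vectors with Lloyd's K-means; rank candidates within
each cluster by Euclidean distance to their centroid and keep the closest
``m_per_cluster`` as keywords; featurize each post by its keyword relative
frequencies plus one aggregate rate per cluster.

K-means is implemented literally as the classic Lloyd iteration — initial
centers drawn uniformly among the candidate vectors, nearest-centroid
assignment under Euclidean distance with ties broken toward the lowest
cluster id, mean update, stop when the assignment is stable — because the
keyword-extraction procedure is defined in terms of exactly these steps. An
emptied cluster is re-seeded with the point farthest from its own centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..corpus import Corpus, ValidationError
from .base import FeatureBlock
from .embedding import EmbeddingTable, SkipGramConfig, train_skipgram

__all__ = [
    "KeywordClustering",
    "extract_candidates",
    "kmeans_cluster",
    "select_keywords",
    "wec_block",
    "WecFeaturizer",
    "DEFAULT_POS_KEEP",
]

#: content-word POS tags kept for candidate keywords (noun/verb/adjective)
DEFAULT_POS_KEEP = frozenset({"n", "v", "a"})


@dataclass
class KeywordClustering:
    candidates: list[str]
    assignments: dict[str, int]
    centroids: np.ndarray
    distances: dict[str, float]
    n_iter: int = 0
    inertia: float = 0.0
    selected_keywords: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def members(self, cluster_id: int) -> list[str]:
        return [w for w in self.candidates if self.assignments[w] == cluster_id]


def extract_candidates(
    corpus: Corpus,
    pos_keep: Iterable[str] = DEFAULT_POS_KEEP,
    embeddings: EmbeddingTable | None = None,
) -> list[str]:
    """Unique content-word tokens, optionally restricted to the embedding
    vocabulary (a candidate without a vector cannot be clustered). Returned
    sorted for determinism."""
    pos_keep = set(pos_keep)
    seen: set[str] = set()
    for post in corpus:
        tags = post.pos_tags or ["x"] * len(post.tokens)
        for tok, tag in zip(post.tokens, tags):
            if tag in pos_keep:
                seen.add(tok)
    if embeddings is not None:
        seen = {w for w in seen if w in embeddings}
    return sorted(seen)


def _lloyd(X: np.ndarray, k: int, seed: int, max_iter: int) -> tuple[np.ndarray, np.ndarray, int]:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)  # argmin ties -> lowest cluster id
        for cid in range(k):
            mask = new_assign == cid
            if mask.any():
                centroids[cid] = X[mask].mean(axis=0)
            else:
                # re-seed an emptied cluster with the farthest point
                far = int(np.sqrt(d2[np.arange(n), new_assign]).argmax())
                centroids[cid] = X[far]
                new_assign[far] = cid
        if np.array_equal(new_assign, assign):
            return assign, centroids, it
        assign = new_assign
    return assign, centroids, max_iter


def kmeans_cluster(
    candidates: Sequence[str],
    embeddings: EmbeddingTable,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 10,
) -> KeywordClustering:
    """Cluster candidate keyword vectors with Lloyd's algorithm.

    ``n_init`` independent restarts are run (each the plain Lloyd procedure
    from a fresh random initialization among the candidate vectors) and the
    run with the lowest within-cluster sum of squares is kept — the standard
    guard against Lloyd's local optima.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("no candidate keywords to cluster")
    missing = [w for w in candidates if w not in embeddings]
    if missing:
        raise ValidationError(f"candidates missing from embedding vocabulary: {missing[:5]}")
    if k > len(candidates):
        raise ValidationError(f"k={k} exceeds number of candidates ({len(candidates)})")
    if n_init < 1:
        raise ValidationError("n_init must be >= 1")
    X = np.asarray([embeddings.vector(w) for w in candidates], dtype=float)
    best = None
    for run in range(n_init):
        assign, centroids, n_iter = _lloyd(X, k, seed + run, max_iter)
        wcss = float(((X - centroids[assign]) ** 2).sum())
        if best is None or wcss < best[0]:
            best = (wcss, assign, centroids, n_iter)
    _, assign, centroids, n_iter = best
    dists = np.linalg.norm(X - centroids[assign], axis=1)
    return KeywordClustering(
        candidates=candidates,
        assignments={w: int(c) for w, c in zip(candidates, assign)},
        centroids=centroids,
        distances={w: float(d) for w, d in zip(candidates, dists)},
        n_iter=n_iter,
        inertia=float((dists**2).sum()),
    )


def select_keywords(clustering: KeywordClustering, m_per_cluster: int) -> list[str]:
    """Within each cluster, the ``m_per_cluster`` candidates closest to the
    centroid (ties broken lexicographically), concatenated in cluster order."""
    if m_per_cluster <= 0:
        raise ValidationError("m_per_cluster must be positive")
    selected: list[str] = []
    for cid in range(clustering.k):
        members = clustering.members(cid)
        members.sort(key=lambda w: (clustering.distances[w], w))
        selected.extend(members[:m_per_cluster])
    return selected


def wec_block(
    corpus: Corpus,
    keywords: Sequence[str],
    clustering: KeywordClustering,
    embeddings: EmbeddingTable | None = None,
    representation: str = "frequency",
) -> FeatureBlock:
    """Per-post WEC features.

    ``frequency`` (default): one relative-frequency column per selected
    keyword plus one aggregate column per cluster (the summed rate of that
    cluster's keywords). ``mean-embedding``: the mean embedding vector of the
    selected keywords present in the post (zeros when none are present).
    """
    if len(corpus) == 0:
        raise ValidationError("empty corpus")
    keywords = list(keywords)
    if representation == "mean-embedding":
        if embeddings is None:
            raise ValidationError("mean-embedding representation needs the embedding table")
        dim = embeddings.vectors.shape[1]
        kwset = set(keywords)
        X = np.zeros((len(corpus), dim))
        for i, post in enumerate(corpus):
            present = [t for t in post.tokens if t in kwset]
            if present:
                X[i] = np.mean([embeddings.vector(w) for w in present], axis=0)
        names = [f"wec_dim{j}" for j in range(dim)]
        return FeatureBlock(X, names, ["WEC"] * dim, corpus.ids)
    if representation != "frequency":
        raise ValidationError(f"unknown WEC representation {representation!r}")

    k = clustering.k
    col_idx = {w: j for j, w in enumerate(keywords)}
    X = np.zeros((len(corpus), len(keywords) + k))
    for i, post in enumerate(corpus):
        for tok in post.tokens:
            j = col_idx.get(tok)
            if j is not None:
                X[i, j] += 1
                X[i, len(keywords) + clustering.assignments[tok]] += 1
        X[i] /= len(post.tokens)
    names = [f"wec_kw_{w}" for w in keywords] + [f"wec_cluster{c}" for c in range(k)]
    return FeatureBlock(X, names, ["WEC"] * len(names), corpus.ids)


class WecFeaturizer(BaseEstimator, TransformerMixin):
    """End-to-end WEC transformer: embeddings + clustering learned in ``fit``,
    keyword features emitted by ``transform``.

    Parameters mirror the underlying steps: skip-gram dimensions/window/
    epochs/min-count, number of clusters ``k``, keywords kept per cluster
    ``m_per_cluster``, and the POS tags treated as content words.
    """

    def __init__(self, dim: int = 100, window: int = 5, epochs: int = 5,
                 min_count: int = 2, negative: int = 5, k: int = 10,
                 m_per_cluster: int = 20, pos_keep: frozenset = DEFAULT_POS_KEEP,
                 representation: str = "frequency", seed: int = 0):
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.min_count = min_count
        self.negative = negative
        self.k = k
        self.m_per_cluster = m_per_cluster
        self.pos_keep = pos_keep
        self.representation = representation
        self.seed = seed

    def fit(self, X: Corpus, y=None) -> "WecFeaturizer":
        config = SkipGramConfig(dim=self.dim, window=self.window, epochs=self.epochs,
                                min_count=self.min_count, negative=self.negative,
                                seed=self.seed)
        self.embedding_ = train_skipgram(X, config)
        candidates = extract_candidates(X, self.pos_keep, self.embedding_)
        k = min(self.k, len(candidates))
        if k == 0:
            raise ValidationError("no candidate keywords found")
        self.clustering_ = kmeans_cluster(candidates, self.embedding_, k, seed=self.seed)
        self.keywords_ = select_keywords(self.clustering_, self.m_per_cluster)
        self.clustering_.selected_keywords = list(self.keywords_)
        return self

    def transform(self, X: Corpus) -> FeatureBlock:
        return wec_block(X, self.keywords_, self.clustering_,
                         embeddings=self.embedding_, representation=self.representation)
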