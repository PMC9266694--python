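import itertools

import numpy as np
import pytest

from sidfuse.corpus import Corpus, Post, ValidationError
from sidfuse.features.embedding import EmbeddingTable, SkipGramConfig, train_skipgram
from sidfuse.features.wec import (
    KeywordClustering,
    WecFeaturizer,
    extract_candidates,
    kmeans_cluster,
    select_keywords,
    wec_block,
)


# ---------------------------------------------------------------------------
# skip-gram embeddings


@pytest.fixture(scope="module")
def toy_embedding():
    """50-post corpus with four disjoint background topics; 'alpha' and
    'beta' appear only adjacent to each other, in a random topic context."""
    rng = np.random.default_rng(0)
    pools = [[f"bg{p}{i}" for i in range(5)] for p in range(4)]
    posts = []
    for i in range(50):
        pool = pools[int(rng.integers(4))]
        others = [str(t) for t in rng.choice(pool, size=6, replace=True)]
        if rng.random() < 0.3:
            cut = int(rng.integers(0, 7))
            tokens = others[:cut] + ["alpha", "beta"] + others[cut:]
        else:
            tokens = others
        posts.append(Post(id=f"t{i}", tokens=tokens, hour=1))
    corpus = Corpus(posts)
    emb = train_skipgram(corpus, SkipGramConfig(dim=16, epochs=5, min_count=1, seed=1))
    return corpus, emb


def test_cooccurring_pair_is_closer_than_median_pair(toy_embedding):
    """The exclusively co-occurring pair sits well above the corpus-median
    pairwise cosine similarity (full similarity matrix as the oracle)."""
    _, emb = toy_embedding
    sims = [emb.cosine(a, b) for a, b in itertools.combinations(emb.vocabulary, 2)]
    assert emb.cosine("alpha", "beta") > np.median(sims)


def test_min_count_drops_rare_words():
    posts = [Post(id=f"p{i}", tokens=["common", "common", "fill"], hour=1) for i in range(5)]
    posts.append(Post(id="q", tokens=["rare", "common"], hour=1))
    emb = train_skipgram(Corpus(posts), SkipGramConfig(dim=8, epochs=2, min_count=2, seed=0))
    assert "common" in emb and "rare" not in emb


def test_same_seed_gives_identical_vectors(toy_embedding):
    corpus, emb = toy_embedding
    again = train_skipgram(corpus, SkipGramConfig(dim=16, epochs=5, min_count=1, seed=1))
    assert np.array_equal(emb.vectors, again.vectors)
    other = train_skipgram(corpus, SkipGramConfig(dim=16, epochs=5, min_count=1, seed=2))
    assert not np.array_equal(emb.vectors, other.vectors)


def test_word2vec_text_round_trip(tmp_path, toy_embedding):
    _, emb = toy_embedding
    path = tmp_path / "vectors.txt"
    emb.save(path)
    back = EmbeddingTable.load(path)
    assert back.vocabulary == emb.vocabulary
    assert np.allclose(back.vectors, emb.vectors, rtol=1e-6, atol=1e-8)


def test_empty_vocabulary_is_an_error():
    corpus = Corpus([Post(id="p", tokens=["once"], hour=1)])
    with pytest.raises(ValidationError):
        train_skipgram(corpus, SkipGramConfig(min_count=2))


# ---------------------------------------------------------------------------
# candidate extraction


def test_candidates_are_unique_content_words_in_vocabulary(toy_embedding):
    corpus = Corpus([
        Post(id="a", tokens=["alpha", "alpha", "beta", "junk"],
             pos_tags=["n", "n", "v", "u"], hour=1),
        Post(id="b", tokens=["alpha", "ghost"], pos_tags=["n", "n"], hour=1),
    ])
    _, emb = toy_embedding
    cands = extract_candidates(corpus, {"n", "v"}, emb)
    assert cands == ["alpha", "beta"]  # deduplicated; 'ghost' not in vocab


def test_all_function_words_gives_empty_candidates():
    corpus = Corpus([Post(id="a", tokens=["x", "y"], pos_tags=["u", "u"], hour=1)])
    assert extract_candidates(corpus, {"n"}) == []


# ---------------------------------------------------------------------------
# K-means against brute force


def table(points):
    vocab = [f"w{i}" for i in range(len(points))]
    vectors = np.array([[x, 1.0] for x in points])
    return vocab, EmbeddingTable(vocab, vectors)


def brute_partitions(points, k, weights=None):
    """Exact optimum over all surjective assignments; returns (wcss, centroids)."""
    pts = np.asarray(points, dtype=float)
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    best = (np.inf, None)
    for assign in itertools.product(range(k), repeat=len(pts)):
        if len(set(assign)) < k:
            continue
        a = np.asarray(assign)
        wcss, cents = 0.0, []
        for c in range(k):
            mask = a == c
            mu = np.average(pts[mask], weights=w[mask])
            wcss += float((w[mask] * (pts[mask] - mu) ** 2).sum())
            cents.append(mu)
        if wcss < best[0]:
            best = (wcss, sorted(cents))
    return best


def test_two_well_separated_pairs_recover_bruteforce_optimum():
    points = [0.0, 0.1, 10.0, 10.1]
    vocab, emb = table(points)
    cl = kmeans_cluster(vocab, emb, k=2, seed=0)
    groups = {frozenset(cl.members(c)) for c in range(2)}
    assert groups == {frozenset({"w0", "w1"}), frozenset({"w2", "w3"})}
    opt_wcss, opt_centroids = brute_partitions(points, 2)
    assert cl.inertia == pytest.approx(opt_wcss)
    assert sorted(cl.centroids[:, 0]) == pytest.approx(opt_centroids)


def test_k_equals_n_gives_singleton_clusters_with_zero_distance():
    vocab, emb = table([0.0, 1.0, 2.0, 5.0])
    cl = kmeans_cluster(vocab, emb, k=4, seed=3)
    assert sorted(cl.assignments.values()) == [0, 1, 2, 3]
    assert all(d == 0 for d in cl.distances.values())


def test_k_larger_than_n_is_an_error():
    vocab, emb = table([0.0, 1.0])
    with pytest.raises(ValidationError):
        kmeans_cluster(vocab, emb, k=3)


def test_duplicated_points_match_weighted_dedup_oracle():
    points = [0.0, 0.0, 0.1, 10.0, 10.0, 10.1]
    vocab, emb = table(points)
    cl = kmeans_cluster(vocab, emb, k=2, seed=1)
    _, dup_centroids = brute_partitions(points, 2)
    _, dedup_centroids = brute_partitions([0.0, 0.1, 10.0, 10.1], 2, weights=[2, 1, 2, 1])
    assert dup_centroids == pytest.approx(dedup_centroids)
    assert sorted(cl.centroids[:, 0]) == pytest.approx(dup_centroids)


def test_restarts_never_worsen_single_run_objective():
    rng = np.random.default_rng(7)
    points = list(rng.normal(0, 1, 12))
    vocab, emb = table(points)
    multi = kmeans_cluster(vocab, emb, k=3, seed=5, n_init=10)
    single = kmeans_cluster(vocab, emb, k=3, seed=5, n_init=1)
    assert multi.inertia <= single.inertia + 1e-12


def test_objective_comparable_to_sklearn_kmeans():
    """Independent cross-check: the library clustering cannot be much worse
    than sklearn's k-means++ on the same instance."""
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(11)
    X = rng.normal(0, 1, (30, 3))
    vocab = [f"w{i}" for i in range(30)]
    emb = EmbeddingTable(vocab, X)
    ours = kmeans_cluster(vocab, emb, k=4, seed=2)
    ref = KMeans(n_clusters=4, n_init=10, random_state=2).fit(X)
    assert ours.inertia <= ref.inertia_ * 1.01


# ---------------------------------------------------------------------------
# keyword selection and featurization


def manual_clustering():
    return KeywordClustering(
        candidates=["a", "b", "c", "d", "e"],
        assignments={"a": 0, "b": 0, "c": 1, "d": 1, "e": 1},
        centroids=np.zeros((2, 2)),
        distances={"a": 0.1, "b": 0.3, "c": 0.2, "d": 0.2, "e": 0.5},
    )


def test_keywords_ranked_by_distance_with_lexicographic_ties():
    cl = manual_clustering()
    assert select_keywords(cl, 1) == ["a", "c"]  # c ties d at 0.2, c wins
    assert select_keywords(cl, 10) == ["a", "b", "c", "d", "e"]  # m >= cluster size


def test_keyword_count_is_m_times_full_clusters():
    cl = KeywordClustering(
        candidates=list("abcdef"),
        assignments={w: i // 2 for i, w in enumerate("abcdef")},
        centroids=np.zeros((3, 2)),
        distances={w: 0.1 * i for i, w in enumerate("abcdef")},
    )
    assert len(select_keywords(cl, 2)) == 6


def test_wec_block_columns_and_cluster_aggregates():
    cl = manual_clustering()
    keywords = select_keywords(cl, 2)  # a, b, c, d
    corpus = Corpus([
        Post(id="p1", tokens=["a", "b", "c", "x"], hour=1),
        Post(id="p2", tokens=["x", "y"], hour=1),
    ])
    block = wec_block(corpus, keywords, cl)
    assert block.n_features == len(keywords) + 2
    assert set(block.column_block) == {"WEC"}
    assert np.all(block.matrix[1] == 0)
    kw_cols = {w: block.column_names.index(f"wec_kw_{w}") for w in keywords}
    agg0 = block.matrix[:, block.column_names.index("wec_cluster0")]
    summed = block.matrix[:, [kw_cols["a"], kw_cols["b"]]].sum(axis=1)
    assert np.allclose(agg0, summed)


def test_mean_embedding_representation(toy_embedding):
    _, emb = toy_embedding
    cl = KeywordClustering(
        candidates=["alpha", "beta"],
        assignments={"alpha": 0, "beta": 0},
        centroids=np.zeros((1, 16)),
        distances={"alpha": 0.0, "beta": 0.0},
    )
    corpus = Corpus([
        Post(id="p1", tokens=["alpha", "beta"], hour=1),
        Post(id="p2", tokens=["bg00"], hour=1),
    ])
    block = wec_block(corpus, ["alpha", "beta"], cl, embeddings=emb,
                      representation="mean-embedding")
    assert block.shape == (2, 16)
    expected = (emb.vector("alpha") + emb.vector("beta")) / 2
    assert np.allclose(block.matrix[0], expected)
    assert np.all(block.matrix[1] == 0)


def test_wec_featurizer_is_deterministic(small_corpus):
    params = dict(dim=16, epochs=2, k=4, m_per_cluster=5, seed=3)
    a = WecFeaturizer(**params).fit(small_corpus)
    b = WecFeaturizer(**params).fit(small_corpus)
    assert a.keywords_ == b.keywords_
    assert np.array_equal(a.transform(small_corpus).matrix, b.transform(small_corpus).matrix)
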