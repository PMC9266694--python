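"""Skip-gram word embeddings trained with negative sampling (SGNS).

A compact, deterministic word2vec-style trainer: input vectors are updated by
sequential stochastic gradient descent over (center, context) pairs within a
fixed window, against ``negative`` noise words drawn from the unigram
distribution raised to 3/4. Training is strictly single-threaded and driven
by one explicit RNG state, so identical corpus + config + seed give
bit-identical vectors. The inner loop is JIT-compiled with numba when
available and falls back to pure Python otherwise.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..corpus import Corpus, ValidationError

__all__ = ["SkipGramConfig", "EmbeddingTable", "train_skipgram"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap(args[0]) if args and callable(args[0]) else wrap

_NEG_TABLE_SIZE = 100_000
_MAX_EXP = 6.0


@dataclass
class SkipGramConfig:
    dim: int = 100
    window: int = 5
    epochs: int = 5
    min_count: int = 2
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.window <= 0 or self.epochs <= 0:
            raise ValidationError("dim, window and epochs must be positive")
        if self.min_count < 1 or self.negative < 1:
            raise ValidationError("min_count and negative must be >= 1")


@dataclass
class EmbeddingTable:
    vocabulary: list[str]
    vectors: np.ndarray
    config: SkipGramConfig = field(default_factory=SkipGramConfig)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValidationError("vectors not aligned to vocabulary")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValidationError("zero-norm vector in embedding table")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

    def save(self, path: str | Path) -> None:
        """word2vec text format: header line, then 'word v1 ... vd' per line."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"{len(self.vocabulary)} {self.vectors.shape[1]}\n")
            for word, vec in zip(self.vocabulary, self.vectors):
                fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @staticmethod
    def load(path: str | Path) -> "EmbeddingTable":
        path = Path(path)
        with path.open() as fh:
            n, d = map(int, fh.readline().split())
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vectors = np.asarray(rows, dtype=np.float32)
        if len(vocab) != n or vectors.shape[1] != d:
            raise ValidationError("embedding file header disagrees with content")
        return EmbeddingTable(vocab, vectors)


@njit(cache=False)
def _sgns_epochs(data, offsets, w_in, w_out, neg_table, window, negative,
                 alpha0, min_alpha, epochs, seed):  # pragma: no cover - jitted
    dim = w_in.shape[1]
    state = np.uint64(seed * 2 + 1)
    mult = np.uint64(6364136223846793005)
    inc = np.uint64(1442695040888963407)
    table_n = neg_table.shape[0]
    n_tokens = data.shape[0]
    total = np.float64(n_tokens) * epochs
    processed = 0.0
    neu1e = np.zeros(dim, dtype=np.float32)
    for _ in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start, end = offsets[s], offsets[s + 1]
            for pos in range(start, end):
                alpha = alpha0 * (1.0 - processed / total)
                if alpha < min_alpha:
                    alpha = min_alpha
                processed += 1.0
                center = data[pos]
                lo = pos - window
                if lo < start:
                    lo = start
                hi = pos + window + 1
                if hi > end:
                    hi = end
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    context = data[ctx_pos]
                    for j in range(dim):
                        neu1e[j] = 0.0
                    for d_i in range(negative + 1):
                        if d_i == 0:
                            target = context
                            label = 1.0
                        else:
                            state = state * mult + inc
                            r = np.int64((state >> np.uint64(33)) % np.uint64(table_n))
                            target = neg_table[r]
                            if target == context:
                                continue
                            label = 0.0
                        f = 0.0
                        for j in range(dim):
                            f += w_in[center, j] * w_out[target, j]
                        if f > _MAX_EXP:
                            g = (label - 1.0) * alpha
                        elif f < -_MAX_EXP:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + math.exp(-f))) * alpha
                        for j in range(dim):
                            neu1e[j] += g * w_out[target, j]
                            w_out[target, j] += g * w_in[center, j]
                    for j in range(dim):
                        w_in[center, j] += neu1e[j]


def train_skipgram(corpus: Corpus, config: SkipGramConfig | None = None) -> EmbeddingTable:
    """Train SGNS embeddings on the corpus tokens.

    Words occurring fewer than ``min_count`` times are dropped before
    training; raises if nothing survives.
    """
    config = config or SkipGramConfig()
    if len(corpus) == 0:
        raise ValidationError("empty corpus")
    counts = Counter(tok for post in corpus for tok in post.tokens)
    vocab = sorted((w for w, c in counts.items() if c >= config.min_count),
                   key=lambda w: (-counts[w], w))
    if not vocab:
        raise ValidationError("vocabulary empty after min-count filtering")
    index = {w: i for i, w in enumerate(vocab)}

    sentences = []
    for post in corpus:
        ids = [index[t] for t in post.tokens if t in index]
        if ids:
            sentences.append(np.asarray(ids, dtype=np.int32))
    data = np.concatenate(sentences) if sentences else np.empty(0, dtype=np.int32)
    offsets = np.zeros(len(sentences) + 1, dtype=np.int64)
    if sentences:
        offsets[1:] = np.cumsum([len(s) for s in sentences])

    # unigram^0.75 negative-sampling table, word2vec style
    freq = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    cum = np.cumsum(freq / freq.sum())
    neg_table = np.searchsorted(cum, (np.arange(_NEG_TABLE_SIZE) + 0.5) / _NEG_TABLE_SIZE)
    neg_table = neg_table.astype(np.int32)

    rng = np.random.default_rng(config.seed)
    w_in = ((rng.random((len(vocab), config.dim)) - 0.5) / config.dim).astype(np.float32)
    w_out = np.zeros((len(vocab), config.dim), dtype=np.float32)

    _sgns_epochs(data, offsets, w_in, w_out, neg_table,
                 config.window, config.negative,
                 config.alpha, config.min_alpha, config.epochs, config.seed)

    return EmbeddingTable(vocab, w_in, config)
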