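"""Basic statistical characteristics (BSC).

Five sub-blocks computed per post: psycholinguistic category rates (LIWC-style
category lexicon), emotion-word polarity rates, degree-adverb rates at four
intensity levels, emoji counts (risk emojis individually plus a total), and a
one-hot encoding of the posting time over eight three-hour bins of the day.

Word-category features are relative frequencies (count / post length) so that
post length is not a confound; emoji occurrences are rare events and are kept
as absolute counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..corpus import Corpus, Lexicon, ValidationError
from .base import FeatureBlock

__all__ = [
    "liwc_category_features",
    "polarity_features",
    "degree_adverb_features",
    "emoji_features",
    "time_bin_features",
    "bsc_block",
    "BscFeaturizer",
]

N_TIME_BINS = 8


def _check_corpus(corpus: Corpus) -> None:
    if len(corpus) == 0:
        raise ValidationError("empty corpus")


def _category_rates(corpus: Corpus, lexicon: Lexicon, prefix: str) -> FeatureBlock:
    """Relative frequency of each lexicon category per post. A token belonging
    to several categories contributes to every one of them."""
    _check_corpus(corpus)
    cats = sorted(lexicon.categories)
    word_cats = lexicon.category_of()
    col_idx = {c: j for j, c in enumerate(cats)}
    X = np.zeros((len(corpus), len(cats)))
    for i, post in enumerate(corpus):
        for tok in post.tokens:
            for c in word_cats.get(tok, ()):
                X[i, col_idx[c]] += 1
        X[i] /= len(post.tokens)
    return FeatureBlock(X, [f"{prefix}_{c}" for c in cats], ["BSC"] * len(cats), corpus.ids)


def liwc_category_features(corpus: Corpus, lexicon: Lexicon) -> FeatureBlock:
    if lexicon.kind != "category-count":
        raise ValidationError(f"expected category-count lexicon, got {lexicon.kind!r}")
    return _category_rates(corpus, lexicon, "bsc_liwc")


def polarity_features(corpus: Corpus, polarity: Lexicon) -> FeatureBlock:
    if polarity.kind != "polarity":
        raise ValidationError(f"expected polarity lexicon, got {polarity.kind!r}")
    block = _category_rates(corpus, polarity, "bsc_pol")
    # fixed column order: positive then negative
    order = [block.column_names.index("bsc_pol_positive"), block.column_names.index("bsc_pol_negative")]
    return block.take_columns(order)


def degree_adverb_features(corpus: Corpus, degrees: Lexicon) -> FeatureBlock:
    if degrees.kind != "degree-adverb":
        raise ValidationError(f"expected degree-adverb lexicon, got {degrees.kind!r}")
    return _category_rates(corpus, degrees, "bsc_deg")


def emoji_features(corpus: Corpus, emoji_lex: Lexicon) -> FeatureBlock:
    """Absolute count of each listed risk emoji plus a total-emoji count.

    Emojis not listed in the lexicon count only toward the total column.
    """
    _check_corpus(corpus)
    if emoji_lex.kind != "emoji":
        raise ValidationError(f"expected emoji lexicon, got {emoji_lex.kind!r}")
    risk = sorted(emoji_lex.categories.get("risk", set()))
    col_idx = {e: j for j, e in enumerate(risk)}
    X = np.zeros((len(corpus), len(risk) + 1))
    for i, post in enumerate(corpus):
        for e in post.emojis:
            if e in col_idx:
                X[i, col_idx[e]] += 1
            X[i, -1] += 1
    names = [f"bsc_emoji_{e}" for e in risk] + ["bsc_emoji_total"]
    return FeatureBlock(X, names, ["BSC"] * len(names), corpus.ids)


def time_bin_features(corpus: Corpus) -> FeatureBlock:
    """One-hot over 8 three-hour bins; bin i covers hours [3i, 3i+3)."""
    _check_corpus(corpus)
    X = np.zeros((len(corpus), N_TIME_BINS))
    for i, post in enumerate(corpus):
        if post.hour is None:
            raise ValidationError(f"post {post.id!r}: missing timestamp")
        X[i, post.hour // 3] = 1.0
    names = [f"bsc_time_bin{i}" for i in range(N_TIME_BINS)]
    return FeatureBlock(X, names, ["BSC"] * N_TIME_BINS, corpus.ids)


def bsc_block(corpus: Corpus, lexicons: Sequence[Lexicon] | Mapping[str, Lexicon]) -> FeatureBlock:
    """All five BSC sub-blocks, horizontally concatenated."""
    if isinstance(lexicons, Mapping):
        lexicons = list(lexicons.values())
    by_kind = {lex.kind: lex for lex in lexicons}
    for kind in ("category-count", "polarity", "degree-adverb", "emoji"):
        if kind not in by_kind:
            raise ValidationError(f"bsc_block: missing {kind!r} lexicon")
    return FeatureBlock.hstack(
        [
            liwc_category_features(corpus, by_kind["category-count"]),
            polarity_features(corpus, by_kind["polarity"]),
            degree_adverb_features(corpus, by_kind["degree-adverb"]),
            emoji_features(corpus, by_kind["emoji"]),
            time_bin_features(corpus),
        ]
    )


class BscFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from a :class:`~sidfuse.corpus.Corpus` to the BSC block.

    Stateless apart from the lexicons it is constructed with; ``fit`` is a
    no-op kept for pipeline compatibility.
    """

    def __init__(self, liwc: Lexicon = None, polarity: Lexicon = None,
                 degrees: Lexicon = None, emojis: Lexicon = None):
        self.liwc = liwc
        self.polarity = polarity
        self.degrees = degrees
        self.emojis = emojis

    def fit(self, X: Corpus, y=None) -> "BscFeaturizer":
        for name in ("liwc", "polarity", "degrees", "emojis"):
            if getattr(self, name) is None:
                raise ValidationError(f"BscFeaturizer: lexicon {name!r} not provided")
        self.n_features_out_ = self.transform(X).n_features
        return self

    def transform(self, X: Corpus) -> FeatureBlock:
        return bsc_block(X, [self.liwc, self.polarity, self.degrees, self.emojis])
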