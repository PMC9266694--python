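"""Risk factors for suicide (RFS).

Per-post relative frequencies over the 13 categories of a suicide-risk
dictionary (self-harm methods, trauma and life pressure, relatives and
friends, psychiatric and somatic symptoms, anger/hopelessness/shame, ...),
plus one overall risk-word rate. When the dictionary's categories are
disjoint the overall rate equals the sum of the category rates.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..corpus import Corpus, Lexicon, ValidationError
from .base import FeatureBlock

__all__ = ["rfs_block", "RfsFeaturizer"]


def rfs_block(corpus: Corpus, risk_dict: Lexicon) -> FeatureBlock:
    """13 per-category rate columns + 1 overall risk-word rate, tagged RFS."""
    if len(corpus) == 0:
        raise ValidationError("empty corpus")
    if risk_dict.kind != "risk-dictionary":
        raise ValidationError(f"expected risk-dictionary lexicon, got {risk_dict.kind!r}")
    cats = sorted(risk_dict.categories)
    word_cats = risk_dict.category_of()
    col_idx = {c: j for j, c in enumerate(cats)}
    X = np.zeros((len(corpus), len(cats) + 1))
    for i, post in enumerate(corpus):
        for tok in post.tokens:
            hit = word_cats.get(tok)
            if hit:
                for c in hit:
                    X[i, col_idx[c]] += 1
                X[i, -1] += 1
        X[i] /= len(post.tokens)
    names = [f"rfs_{c}" for c in cats] + ["rfs_total"]
    return FeatureBlock(X, names, ["RFS"] * len(names), corpus.ids)


class RfsFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from a Corpus to the RFS block."""

    def __init__(self, risk_dict: Lexicon = None):
        self.risk_dict = risk_dict

    def fit(self, X: Corpus, y=None) -> "RfsFeaturizer":
        if self.risk_dict is None:
            raise ValidationError("RfsFeaturizer: risk_dict not provided")
        self.n_features_out_ = self.transform(X).n_features
        return self

    def transform(self, X: Corpus) -> FeatureBlock:
        return rfs_block(X, self.risk_dict)
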