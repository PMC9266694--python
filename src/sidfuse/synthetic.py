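"""Synthetic corpora with the statistical structure of an imbalanced
suicidal-ideation dataset.

The real data this package targets — short Chinese microblog posts, of which
roughly 5.6% express suicidal ideation — are not publicly released. This
module generates labeled corpora that reproduce the *statistical* structure
the detection pipeline relies on, so every downstream stage can be exercised
and tested end to end:

* an exact class split (default 2,272 positive / 37,950 negative posts);
* class-conditional enrichment of suicide-risk-dictionary words, negative
  emotion words, degree adverbs and risk emojis in the positive class;
* a night-skewed posting-time distribution for the positive class;
* latent-topic co-occurrence structure, so that skip-gram embeddings trained
  on the corpus place words of one topic — in particular the risk-affine
  topic and the risk vocabulary that accompanies it — near each other.

Tokens are synthetic identifiers, not natural language: linguistic
plausibility is a non-goal, distributional structure is the point.

All randomness flows from the single ``seed`` in :class:`GeneratorConfig`
through one ``numpy`` generator; identical configs produce byte-identical
corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import Corpus, Lexicon, Post, ValidationError

__all__ = ["GeneratorConfig", "default_enrichment", "make_fixture_lexicons", "generate_corpus"]

LIWC_CATEGORIES = ("affect", "cognition", "social", "body", "work", "leisure", "family")
DEGREE_LEVELS = ("level1", "level2", "level3", "level4")
RISK_CATEGORIES = tuple(f"risk{i:02d}" for i in range(1, 14))
RISK_EMOJIS = ("Drugs", "Knife", "Rope")
OTHER_EMOJIS = ("Smile", "Heart", "Sun", "Moon", "Cry", "Star")

# content-word POS tags cycle over noun/verb/adjective; adverbs and filler
# function words get their own tags so POS-based candidate filtering is real
CONTENT_TAGS = ("n", "v", "a")


def default_enrichment() -> dict[str, float]:
    """Positive-class rate multipliers per lexicon category.

    Risk-dictionary words are the strongest class marker, negative emotion
    words next; positive emotion words are depleted. Values are the package's
    fixed emulation of class-conditional lexical usage.
    """
    enrich = {cat: 4.0 for cat in RISK_CATEGORIES}
    enrich.update({"negative": 3.0, "positive": 0.5, "affect": 2.5})
    enrich.update({lvl: 1.5 for lvl in DEGREE_LEVELS})
    return enrich


def _base_rates() -> dict[str, float]:
    rates = {cat: 0.010 for cat in LIWC_CATEGORIES}
    rates.update({"positive": 0.030, "negative": 0.030})
    rates.update({lvl: 0.005 for lvl in DEGREE_LEVELS})
    rates.update({cat: 0.004 for cat in RISK_CATEGORIES})
    return rates


@dataclass
class GeneratorConfig:
    n_pos: int = 2272
    n_neg: int = 37950
    seed: int = 0

    # lexicon family sizes
    liwc_words_per_category: int = 12
    polarity_words: int = 40
    degree_words_per_level: int = 6
    risk_words_per_category: int = 10

    # post length: rounded log-normal, mean ~25 tokens
    mean_post_length: float = 25.0
    sd_log_length: float = 0.4

    # per-token draw probability of each lexicon category in the negative
    # class; positive class multiplies by `enrichment`
    base_rates: dict[str, float] = field(default_factory=_base_rates)
    enrichment: dict[str, float] = field(default_factory=default_enrichment)

    # latent topics: background words co-occur within their topic; topic 0 is
    # the risk-affine topic the positive class prefers
    n_topics: int = 8
    topic_vocab_size: int = 30
    pos_risk_topic_prob: float = 0.45
    neg_risk_topic_prob: float = 0.08

    filler_rate: float = 0.15
    n_filler_words: int = 15

    # emoji behaviour
    emoji_rate: float = 0.7
    pos_risk_emoji_prob: float = 0.35
    neg_risk_emoji_prob: float = 0.10

    # per-class distribution over the 8 three-hour bins of the day; the
    # positive class skews toward late-night bins (sleep-disruption signal)
    pos_time_probs: tuple[float, ...] = (0.20, 0.15, 0.07, 0.08, 0.08, 0.10, 0.12, 0.20)
    neg_time_probs: tuple[float, ...] = (0.06, 0.04, 0.10, 0.16, 0.16, 0.16, 0.16, 0.16)

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValidationError("n_pos and n_neg must be positive")
        if any(m <= 0 for m in self.enrichment.values()):
            raise ValidationError("enrichment multipliers must be > 0")
        for probs in (self.pos_time_probs, self.neg_time_probs):
            if len(probs) != 8 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError("time-bin distributions must have 8 entries summing to 1")
        for name in (
            "liwc_words_per_category",
            "polarity_words",
            "degree_words_per_level",
            "risk_words_per_category",
            "n_topics",
            "topic_vocab_size",
            "n_filler_words",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def scaled(self, n_pos: int, n_neg: int, **overrides) -> "GeneratorConfig":
        """A copy with a different corpus size (and optional field overrides)."""
        return replace(self, n_pos=n_pos, n_neg=n_neg, **overrides)


def make_fixture_lexicons(config: GeneratorConfig) -> list[Lexicon]:
    """Build the five synthetic lexicon families the featurizers consume.

    Entry sets use distinct prefixes per family, so they are disjoint from
    each other and from the background topic vocabulary by construction.
    Deterministic: depends only on the size fields of ``config``.
    """
    liwc = Lexicon(
        "liwc-style",
        {
            cat: {f"{cat}_w{i:02d}" for i in range(config.liwc_words_per_category)}
            for cat in LIWC_CATEGORIES
        },
        kind="category-count",
    )
    polarity = Lexicon(
        "polarity",
        {
            "positive": {f"posw{i:02d}" for i in range(config.polarity_words)},
            "negative": {f"negw{i:02d}" for i in range(config.polarity_words)},
        },
        kind="polarity",
    )
    degrees = Lexicon(
        "degree-adverbs",
        {
            lvl: {f"{lvl}_adv{i}" for i in range(config.degree_words_per_level)}
            for lvl in DEGREE_LEVELS
        },
        kind="degree-adverb",
    )
    emojis = Lexicon(
        "emojis",
        {"risk": set(RISK_EMOJIS), "other": set(OTHER_EMOJIS)},
        kind="emoji",
    )
    risk = Lexicon(
        "risk-dictionary",
        {
            cat: {f"{cat}_w{i:02d}" for i in range(config.risk_words_per_category)}
            for cat in RISK_CATEGORIES
        },
        kind="risk-dictionary",
    )
    return [liwc, polarity, degrees, emojis, risk]


def _pos_tag_for(word: str) -> str:
    """Fixed POS tag per vocabulary word: adverb levels 'd', filler 'u',
    all other (content) words cycle n/v/a by a stable hash of the word."""
    if word.startswith("level"):
        return "d"
    if word.startswith("fill"):
        return "u"
    return CONTENT_TAGS[sum(word.encode()) % len(CONTENT_TAGS)]


def generate_corpus(config: GeneratorConfig, lexicons: Sequence[Lexicon]) -> Corpus:
    """Draw a labeled corpus under the class-conditional mixture model.

    Each post picks one latent topic (the positive class prefers the
    risk-affine topic 0), then draws tokens independently: each token comes
    from lexicon category ``c`` with probability ``base_rate[c] *
    enrichment[c]**label``, from a small filler vocabulary with probability
    ``filler_rate``, and otherwise from the post's topic vocabulary.
    """
    rng = np.random.default_rng(config.seed)
    by_kind = {lex.kind: lex for lex in lexicons}
    required = {"category-count", "polarity", "degree-adverb", "emoji", "risk-dictionary"}
    missing = required - set(by_kind)
    if missing:
        raise ValidationError(f"missing lexicon kinds: {sorted(missing)}")

    cat_words: dict[str, list[str]] = {}
    for kind in ("category-count", "polarity", "degree-adverb", "risk-dictionary"):
        for cat, entries in by_kind[kind].categories.items():
            cat_words[cat] = sorted(entries)
    categories = [c for c in config.base_rates if c in cat_words]

    topics = [
        [f"top{t}_w{i:02d}" for i in range(config.topic_vocab_size)]
        for t in range(config.n_topics)
    ]
    filler = [f"fill{i:02d}" for i in range(config.n_filler_words)]
    risk_emojis = sorted(by_kind["emoji"].categories.get("risk", set()))
    other_emojis = sorted(by_kind["emoji"].categories.get("other", set()))

    mu = math.log(config.mean_post_length) - config.sd_log_length**2 / 2

    def class_source_probs(label: int) -> np.ndarray:
        probs = np.array(
            [
                config.base_rates[c] * (config.enrichment.get(c, 1.0) if label == 1 else 1.0)
                for c in categories
            ]
        )
        total = probs.sum() + config.filler_rate
        if total >= 1.0:
            raise ValidationError("lexicon draw rates plus filler rate must sum to < 1")
        # last two sources: filler, topic
        return np.concatenate([probs, [config.filler_rate, 1.0 - total]])

    source_probs = {0: class_source_probs(0), 1: class_source_probs(1)}

    def topic_probs(label: int) -> np.ndarray:
        p_risk = config.pos_risk_topic_prob if label == 1 else config.neg_risk_topic_prob
        probs = np.full(config.n_topics, (1.0 - p_risk) / max(config.n_topics - 1, 1))
        probs[0] = p_risk
        return probs

    tprobs = {0: topic_probs(0), 1: topic_probs(1)}
    time_probs = {0: np.asarray(config.neg_time_probs), 1: np.asarray(config.pos_time_probs)}

    labels = np.array([1] * config.n_pos + [0] * config.n_neg)
    rng.shuffle(labels)

    n_sources = len(categories) + 2
    posts: list[Post] = []
    for i, label in enumerate(labels):
        label = int(label)
        topic = int(rng.choice(config.n_topics, p=tprobs[label]))
        length = max(3, int(round(rng.lognormal(mu, config.sd_log_length))))
        sources = rng.choice(n_sources, size=length, p=source_probs[label])
        tokens = []
        for s in sources:
            if s < len(categories):
                pool = cat_words[categories[s]]
            elif s == len(categories):
                pool = filler
            else:
                pool = topics[topic]
            tokens.append(pool[int(rng.integers(len(pool)))])
        tags = [_pos_tag_for(t) for t in tokens]

        n_emoji = int(rng.poisson(config.emoji_rate))
        p_risk = config.pos_risk_emoji_prob if label == 1 else config.neg_risk_emoji_prob
        emojis = []
        for _ in range(n_emoji):
            if rng.random() < p_risk and risk_emojis:
                emojis.append(risk_emojis[int(rng.integers(len(risk_emojis)))])
            elif other_emojis:
                emojis.append(other_emojis[int(rng.integers(len(other_emojis)))])

        tbin = int(rng.choice(8, p=time_probs[label]))
        hour = 3 * tbin + int(rng.integers(3))
        minute = int(rng.integers(60))

        posts.append(
            Post(
                id=f"p{i:06d}",
                tokens=tokens,
                pos_tags=tags,
                hour=hour,
                minute=minute,
                emojis=emojis,
                label=label,
            )
        )

    return Corpus(posts, provenance=f"synthetic:{config.seed}")
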