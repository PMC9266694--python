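"""Posts, lexicons and their on-disk formats.

A :class:`Post` is one short social-media message: its tokens (pre-segmented;
segmentation itself is pluggable, see :class:`Tokenizer`), part-of-speech tags
aligned to the tokens, a time-of-day stamp, emoji identifiers and an optional
binary label (1 = expresses suicidal ideation, 0 = does not).

A :class:`Lexicon` maps category names to entry sets and carries a ``kind``
that fixes its structural contract: a degree-adverb lexicon has exactly four
intensity levels and a suicide-risk dictionary exactly thirteen categories.

Corpora are stored as JSONL (canonical) or CSV (convenience, list fields
``|``-joined); lexicons as TSV (``category<TAB>entry`` per line) or JSON
(category -> list of entries).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

__all__ = [
    "Post",
    "Lexicon",
    "Corpus",
    "ValidationError",
    "CorpusFormatError",
    "Tokenizer",
    "identity_tokenizer",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "write_lexicon",
    "merge_polarity_lexicons",
]

LEXICON_KINDS = (
    "category-count",
    "polarity",
    "degree-adverb",
    "emoji",
    "risk-dictionary",
)

N_DEGREE_LEVELS = 4
N_RISK_CATEGORIES = 13


class ValidationError(ValueError):
    """An invariant of the data model is violated."""


class CorpusFormatError(ValueError):
    """A corpus file cannot be parsed; the message names row and field."""


#: A tokenizer turns raw text into aligned (tokens, pos_tags). The default
#: pipeline assumes pre-segmented input; plugging in a real segmenter (e.g.
#: jieba for Chinese) is a one-liner for callers that need it.
Tokenizer = Callable[[str], tuple[list[str], list[str]]]


def identity_tokenizer(text: str) -> tuple[list[str], list[str]]:
    """Whitespace-split fallback for already-segmented text; tags unknown ('x')."""
    tokens = text.split()
    return tokens, ["x"] * len(tokens)


@dataclass
class Post:
    id: str
    tokens: list[str]
    pos_tags: list[str] | None = None
    text: str = ""
    hour: int = 0
    minute: int = 0
    emojis: list[str] = field(default_factory=list)
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError(f"post {self.id!r}: empty token list")
        if self.pos_tags is not None and len(self.pos_tags) != len(self.tokens):
            raise ValidationError(
                f"post {self.id!r}: {len(self.pos_tags)} POS tags for "
                f"{len(self.tokens)} tokens"
            )
        if not (0 <= self.hour < 24 and 0 <= self.minute < 60):
            raise ValidationError(
                f"post {self.id!r}: invalid time {self.hour:02d}:{self.minute:02d}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"post {self.id!r}: label {self.label!r} not in {{0,1}}")


@dataclass
class Lexicon:
    name: str
    categories: dict[str, set[str]]
    kind: str = "category-count"

    def __post_init__(self) -> None:
        if self.kind not in LEXICON_KINDS:
            raise ValidationError(f"unknown lexicon kind {self.kind!r}")
        for cat, entries in self.categories.items():
            self.categories[cat] = {str(e) for e in entries}
            if any(not e for e in self.categories[cat]):
                raise ValidationError(f"lexicon {self.name!r}: empty entry in {cat!r}")
        if self.kind == "degree-adverb" and len(self.categories) != N_DEGREE_LEVELS:
            raise ValidationError(
                f"degree-adverb lexicon {self.name!r} has {len(self.categories)} "
                f"categories, expected {N_DEGREE_LEVELS}"
            )
        if self.kind == "risk-dictionary" and len(self.categories) != N_RISK_CATEGORIES:
            raise ValidationError(
                f"risk-dictionary lexicon {self.name!r} has {len(self.categories)} "
                f"categories, expected {N_RISK_CATEGORIES}"
            )

    def category_of(self) -> dict[str, list[str]]:
        """Invert the mapping: word -> list of categories containing it."""
        out: dict[str, list[str]] = {}
        for cat in self.categories:
            for word in self.categories[cat]:
                out.setdefault(word, []).append(cat)
        return out

    @property
    def words(self) -> set[str]:
        return set().union(*self.categories.values()) if self.categories else set()


@dataclass
class Corpus:
    posts: list[Post]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = Counter(p.id for p in self.posts)
        dupes = [pid for pid, n in seen.items() if n > 1]
        if dupes:
            raise ValidationError(f"duplicate post ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.posts]

    def labels(self):
        import numpy as np

        if any(p.label is None for p in self.posts):
            raise ValidationError("corpus contains unlabeled posts")
        return np.asarray([p.label for p in self.posts], dtype=int)


# ---------------------------------------------------------------------------
# corpus I/O

_CORPUS_FIELDS = ("id", "text", "tokens", "pos", "time", "emojis", "label")


def _parse_time(value: str) -> tuple[int, int]:
    parts = str(value).split(":")
    if len(parts) != 2:
        raise ValueError(f"time {value!r} not HH:MM")
    hour, minute = int(parts[0]), int(parts[1])
    if not (0 <= hour < 24 and 0 <= minute < 60):
        raise ValueError(f"time {value!r} out of range")
    return hour, minute


def _post_from_record(rec: dict, row: int) -> Post:
    for key in ("id", "tokens", "time"):
        if key not in rec or rec[key] in (None, ""):
            raise CorpusFormatError(f"row {row}: missing required field {key!r}")
    try:
        hour, minute = _parse_time(rec["time"])
    except ValueError as exc:
        raise CorpusFormatError(f"row {row}: {exc}") from None
    label = rec.get("label")
    if label in (None, ""):
        label = None
    else:
        label = int(label)
    try:
        return Post(
            id=str(rec["id"]),
            text=str(rec.get("text", "") or ""),
            tokens=list(rec["tokens"]),
            pos_tags=list(rec["pos"]) if rec.get("pos") else None,
            hour=hour,
            minute=minute,
            emojis=list(rec.get("emojis") or []),
            label=label,
        )
    except ValidationError as exc:
        raise CorpusFormatError(f"row {row}: {exc}") from None


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL or CSV; ``format`` inferred from the suffix."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    posts: list[Post] = []
    if fmt == "jsonl":
        with path.open() as fh:
            for row, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"row {row}: invalid JSON ({exc})") from None
                posts.append(_post_from_record(rec, row))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(_CORPUS_FIELDS) - set(reader.fieldnames or [])
            if missing:
                raise CorpusFormatError(f"missing columns: {sorted(missing)}")
            for row, rec in enumerate(reader):
                rec = dict(rec)
                for key in ("tokens", "pos", "emojis"):
                    rec[key] = rec[key].split("|") if rec[key] else []
                posts.append(_post_from_record(rec, row))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return Corpus(posts, provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with path.open("w") as fh:
            for p in corpus:
                rec = {
                    "id": p.id,
                    "text": p.text,
                    "tokens": p.tokens,
                    "pos": p.pos_tags or [],
                    "time": f"{p.hour:02d}:{p.minute:02d}",
                    "emojis": p.emojis,
                    "label": p.label,
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CORPUS_FIELDS)
            for p in corpus:
                writer.writerow(
                    [
                        p.id,
                        p.text,
                        "|".join(p.tokens),
                        "|".join(p.pos_tags or []),
                        f"{p.hour:02d}:{p.minute:02d}",
                        "|".join(p.emojis),
                        "" if p.label is None else p.label,
                    ]
                )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


# ---------------------------------------------------------------------------
# lexicon I/O

def read_lexicon(path: str | Path, kind: str = "category-count", name: str | None = None) -> Lexicon:
    """Read a lexicon from TSV (category<TAB>entry) or JSON (category -> list)."""
    path = Path(path)
    categories: dict[str, set[str]] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for cat, entries in data.items():
            categories.setdefault(cat, set()).update(str(e) for e in entries)
    else:
        with path.open() as fh:
            for lineno, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise CorpusFormatError(f"{path.name} line {lineno}: expected category<TAB>entry")
                categories.setdefault(parts[0], set()).add(parts[1])
    return Lexicon(name=name or path.stem, categories=categories, kind=kind)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = {cat: sorted(entries) for cat, entries in sorted(lexicon.categories.items())}
        path.write_text(json.dumps(data, ensure_ascii=False, indent=1))
    else:
        with path.open("w") as fh:
            for cat in sorted(lexicon.categories):
                for entry in sorted(lexicon.categories[cat]):
                    fh.write(f"{cat}\t{entry}\n")


def merge_polarity_lexicons(lexicons: Sequence[Lexicon], name: str = "polarity-merged") -> Lexicon:
    """Merge several positive/negative word lists into one polarity lexicon.

    A word's polarity is decided by majority vote over the source lexicons that
    contain it; words with tied votes are excluded. Order of the inputs does
    not matter.
    """
    if not lexicons:
        raise ValidationError("merge_polarity_lexicons: empty input list")
    for lex in lexicons:
        if set(lex.categories) != {"positive", "negative"}:
            raise ValidationError(
                f"lexicon {lex.name!r} categories {sorted(lex.categories)} != "
                "['negative', 'positive']"
            )
    votes: dict[str, int] = {}
    for lex in lexicons:
        for word in lex.categories["positive"]:
            votes[word] = votes.get(word, 0) + 1
        for word in lex.categories["negative"]:
            votes[word] = votes.get(word, 0) - 1
    merged = {
        "positive": {w for w, v in votes.items() if v > 0},
        "negative": {w for w, v in votes.items() if v < 0},
    }
    return Lexicon(name=name, categories=merged, kind="polarity")
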