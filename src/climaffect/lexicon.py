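"""Dictionary-based psycholinguistic scoring of short posts.

Posts are scored against a category lexicon in the word-count tradition:
each category's score is the percentage of tokens in the post that match one
of the category's entries.  Entries are literal words or stems marked by a
trailing ``*`` which match any token having the stem as a prefix.  On top of
the raw category percentages the module derives

* the expressed emotional well-being index (``ewb``): positive-affect
  percentage minus negative-affect percentage, in [-100, 100];
* an analytic-thinking composite: an intercept of 30 plus articles and
  prepositions, minus personal/impersonal pronouns, auxiliary verbs,
  conjunctions, adverbs and negations (weights configurable);
* a somatosensory score (default: body + feel percentages);
* a binary pro-environmental flag from a separate seven-category phrase list
  matched as case-folded substrings of the raw text.

Proprietary dictionaries (LIWC and its Simplified-Chinese adaptation) cannot
be redistributed; the module defines an open plain-text lexicon format and
ships a small demonstration lexicon.  Users with a licensed dictionary can
export it to the same format.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Lexicon",
    "ProEnvLexicon",
    "LexiconError",
    "PRO_ENV_CATEGORIES",
    "DEFAULT_ANALYTIC_WEIGHTS",
    "DEFAULT_SOMATOSENSORY_WEIGHTS",
    "read_lexicon",
    "load_toy_lexicon",
    "load_toy_proenv_lexicon",
    "segment",
    "score_post",
    "score_posts",
    "analytic_score",
    "classify_pro_env",
]


class LexiconError(ValueError):
    """Raised for malformed lexicon files or inconsistent composite specs."""


#: The analytic-thinking composite: intercept + signed function-word categories.
DEFAULT_ANALYTIC_WEIGHTS: dict[str, float] = {
    "_intercept": 30.0,
    "article": 1.0,
    "preposition": 1.0,
    "ppron": -1.0,
    "ipron": -1.0,
    "auxverb": -1.0,
    "conj": -1.0,
    "adverb": -1.0,
    "negate": -1.0,
}

#: Somatosensory experience: bodily-process plus perceptual-feeling categories.
DEFAULT_SOMATOSENSORY_WEIGHTS: dict[str, float] = {
    "_intercept": 0.0,
    "body": 1.0,
    "feel": 1.0,
}

#: The seven pro-environmental behaviour keyword groups.
PRO_ENV_CATEGORIES = (
    "saving_energy",
    "consumption",
    "activism",
    "recycling",
    "transportation",
    "diets",
    "waste_management",
)

_PUNCT_TABLE = str.maketrans("", "", string.punctuation + "。，！？；：、“”‘’（）《》")


@dataclass
class Lexicon:
    """A category lexicon: category name -> entries (words or ``stem*``).

    ``summary_weights`` maps a composite score name to a ``{category: weight}``
    mapping with an optional ``_intercept`` key.
    """

    categories: dict[str, frozenset[str]]
    summary_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, entries in self.categories.items():
            if not entries:
                raise LexiconError(f"category {name!r} has no entries")
            for e in entries:
                if "*" in e[:-1] or e == "*":
                    raise LexiconError(
                        f"wildcard only allowed in terminal position: {e!r} in {name!r}"
                    )
        if not self.summary_weights:
            # attach default composites only when their constituents exist
            self.summary_weights = {
                name: dict(w)
                for name, w in (
                    ("analytic", DEFAULT_ANALYTIC_WEIGHTS),
                    ("somatosensory", DEFAULT_SOMATOSENSORY_WEIGHTS),
                )
                if all(c in self.categories for c in w if c != "_intercept")
            }
        self._exact: dict[str, frozenset[str]] = {}
        self._stems: dict[str, tuple[str, ...]] = {}
        for name, entries in self.categories.items():
            self._exact[name] = frozenset(e for e in entries if not e.endswith("*"))
            self._stems[name] = tuple(
                sorted(e[:-1] for e in entries if e.endswith("*"))
            )

    @property
    def vocabulary(self) -> frozenset[str]:
        """Union of all entries with wildcard markers stripped."""
        out: set[str] = set()
        for entries in self.categories.values():
            out.update(e[:-1] if e.endswith("*") else e for e in entries)
        return frozenset(out)

    def matches(self, category: str, token: str) -> bool:
        if token in self._exact[category]:
            return True
        return any(token.startswith(s) for s in self._stems[category])


@dataclass
class ProEnvLexicon:
    """Seven named keyword groups of pro-environmental behaviour phrases."""

    categories: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.categories) != 7:
            raise LexiconError(
                f"pro-environmental lexicon needs exactly 7 categories, "
                f"got {len(self.categories)}"
            )
        for name, phrases in self.categories.items():
            if not phrases:
                raise LexiconError(f"pro-environmental category {name!r} is empty")
        self._phrases = tuple(
            p.casefold() for phrases in self.categories.values() for p in phrases
        )


def _parse_sections(path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                if current in sections:
                    raise LexiconError(f"duplicate category {current!r}")
                sections[current] = []
            elif current is None:
                raise LexiconError(f"entry {line!r} before any [category] header")
            else:
                sections[current].append(line)
    return sections


def read_lexicon(path, summary_weights: dict | None = None) -> Lexicon:
    """Read a lexicon file: ``[category]`` headers, one entry per line."""
    sections = _parse_sections(path)
    return Lexicon(
        categories={k: frozenset(v) for k, v in sections.items()},
        summary_weights=summary_weights or {},
    )


def read_proenv_lexicon(path) -> ProEnvLexicon:
    sections = _parse_sections(path)
    return ProEnvLexicon(categories={k: tuple(v) for k, v in sections.items()})


def load_toy_lexicon() -> Lexicon:
    """The bundled demonstration lexicon (not a licensed dictionary)."""
    with resources.as_file(
        resources.files("climaffect.data").joinpath("toy_lexicon.txt")
    ) as p:
        return read_lexicon(p)


def load_toy_proenv_lexicon() -> ProEnvLexicon:
    with resources.as_file(
        resources.files("climaffect.data").joinpath("toy_proenv_lexicon.txt")
    ) as p:
        return read_proenv_lexicon(p)


def segment(text: str, lexicon: Lexicon, mode: str = "auto") -> list[str]:
    """Tokenize raw text.

    ``whitespace`` mode splits on whitespace and strips punctuation, for
    space-delimited scripts.  ``greedy`` mode runs a maximal forward match
    against the lexicon vocabulary, falling back to single characters, for
    scripts without word delimiters.  ``auto`` picks ``whitespace`` when the
    text contains whitespace and ``greedy`` otherwise.
    """
    if not text:
        return []
    if mode == "auto":
        mode = "whitespace" if re.search(r"\s", text) else "greedy"
    if mode == "whitespace":
        tokens = [t.translate(_PUNCT_TABLE).casefold() for t in text.split()]
        return [t for t in tokens if t]
    if mode != "greedy":
        raise ValueError(f"unknown segmentation mode {mode!r}")
    vocab = lexicon.vocabulary
    max_len = max((len(w) for w in vocab), default=1)
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        for L in range(min(max_len, n - i), 1, -1):
            if text[i : i + L] in vocab:
                tokens.append(text[i : i + L])
                i += L
                break
        else:
            tokens.append(text[i])
            i += 1
    return tokens


def analytic_score(
    category_pct: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Weighted-sum composite of category percentages (raw scale, unclamped)."""
    weights = DEFAULT_ANALYTIC_WEIGHTS if weights is None else weights
    total = float(weights.get("_intercept", 0.0))
    for cat, w in weights.items():
        if cat == "_intercept":
            continue
        if cat not in category_pct:
            raise LexiconError(f"composite references unknown category {cat!r}")
        total += w * category_pct[cat]
    return total


def classify_pro_env(text: str, pel: ProEnvLexicon) -> int:
    """1 iff any phrase from any of the seven groups occurs in the text.

    Phrase match is a case-folded substring test on the raw text, because
    multi-word keyword phrases could be split by tokenization.
    """
    folded = text.casefold()
    return int(any(p in folded for p in pel._phrases))


def score_post(
    tokens: Iterable[str],
    lexicon: Lexicon,
    *,
    text: str | None = None,
    pel: ProEnvLexicon | None = None,
) -> dict[str, float]:
    """Score one tokenized post; returns category percentages and composites.

    A zero-token post scores 0 in every category (composites then reduce to
    their intercepts).  When ``pel`` is given, the raw ``text`` (or the
    space-joined tokens) is additionally classified for pro-environmental
    content.
    """
    tokens = list(tokens)
    n = len(tokens)
    pct: dict[str, float] = {}
    for cat in lexicon.categories:
        if n == 0:
            pct[cat] = 0.0
        else:
            hits = sum(1 for t in tokens if lexicon.matches(cat, t))
            pct[cat] = 100.0 * hits / n
    out = dict(pct)
    out["ewb"] = pct.get("posemo", 0.0) - pct.get("negemo", 0.0)
    for name, weights in lexicon.summary_weights.items():
        out[name] = analytic_score(pct, weights)
    if pel is not None:
        out["pro_env"] = classify_pro_env(
            text if text is not None else " ".join(tokens), pel
        )
    return out


def score_posts(
    posts: pd.DataFrame,
    lexicon: Lexicon,
    pel: ProEnvLexicon | None = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Score a table of posts (columns: post_id, date, region, text or tokens).

    Returns one row per post with id columns, all category percentages, the
    well-being index, composite scores, and the pro-environmental flag when a
    phrase lexicon is supplied.
    """
    records = []
    for row in posts.itertuples(index=False):
        if hasattr(row, "tokens") and row.tokens is not None:
            tokens = list(row.tokens)
            text = getattr(row, "text", None)
        else:
            text = row.text
            tokens = segment(text, lexicon, mode=mode)
        scores = score_post(tokens, lexicon, text=text, pel=pel)
        rec = {"post_id": row.post_id, "date": row.date, "region": row.region}
        rec.update(scores)
        records.append(rec)
    return pd.DataFrame.from_records(records)
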