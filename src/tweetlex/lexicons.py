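"""Keyword lexicons and the tweet-matching predicate.

Three built-in lexicons ship as package data:

* three emotion categories (fear, anxiety, paranoia) whose root keywords were
  manually expanded to all tenses and pluralities;
* thirteen obsessive-compulsive behaviour categories drawn from the
  Yale-Brown Obsessive-Compulsive Scale symptom checklist, expanded the same
  way;
* the self-identification term list used to flag candidate cohort members
  (plain words plus hashtags).

Matching is whole-token and case-insensitive: text is lowercased, split on
whitespace, and leading/trailing punctuation is stripped from each token
except a leading ``#`` (so hashtag terms match literally). The form lists are
closed sets — there is no runtime stemming — so "fearless" does not match the
fear category. Multi-word terms ("spectrum disorders") match as a contiguous
token sequence.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "KeywordCategory",
    "tokenize",
    "match_tweet",
    "match_tokens",
    "builtin_emotion_lexicon",
    "builtin_ocd_lexicon",
    "builtin_asd_identification_terms",
    "lexicon_from_csv",
    "lexicon_to_csv",
    "EMOTION_CATEGORIES",
    "OCD_CATEGORIES",
]

#: Category names in report order.
EMOTION_CATEGORIES = ("fear", "anxiety", "paranoia")
OCD_CATEGORIES = (
    "obsess", "fixate", "repeat", "routine", "freak", "clean", "check",
    "count", "hoard", "wash", "worry", "excess", "concern",
)

# ASCII punctuation plus the unicode quotes/dashes common in tweets.
_PUNCT = frozenset(string.punctuation) | set("‘’“”–—…¡¿")


@dataclass(frozen=True)
class KeywordCategory:
    """A named lexicon category: root keyword(s) and its closed set of forms.

    ``forms`` holds every lowercase surface string that counts as a match.
    Some categories list only derived forms (e.g. the routine category matches
    "routinely"/"routines" but not "routine" itself), mirroring how the
    expansions were curated.
    """

    name: str
    roots: tuple[str, ...]
    forms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.forms:
            raise ValueError(f"category {self.name!r} has no forms")
        bad = [f for f in self.forms if f != f.lower()]
        if bad:
            raise ValueError(f"non-lowercase forms in {self.name!r}: {bad}")


def _clean_token(tok: str) -> str:
    # strip edge punctuation but keep a leading '#' so hashtags survive
    i, j = 0, len(tok)
    while i < j and tok[i] in _PUNCT and tok[i] != "#":
        i += 1
    while j > i and tok[j - 1] in _PUNCT:
        j -= 1
    return tok[i:j]


def tokenize(text: str) -> list[str]:
    """Lowercase and split ``text`` into cleaned whole tokens."""
    out = []
    for raw in text.lower().split():
        tok = _clean_token(raw)
        if tok:
            out.append(tok)
    return out


def _split_forms(forms: Iterable[str]) -> tuple[frozenset[str], tuple[tuple[str, ...], ...]]:
    single, multi = set(), []
    for f in forms:
        parts = tuple(f.split())
        if len(parts) == 1:
            single.add(f)
        else:
            multi.append(parts)
    return frozenset(single), tuple(multi)


def match_tokens(tokens: Sequence[str], forms: Iterable[str]) -> bool:
    """True iff any form occurs among ``tokens`` (multi-word forms as a
    contiguous subsequence)."""
    single, multi = _split_forms(forms)
    if any(t in single for t in tokens):
        return True
    for parts in multi:
        k = len(parts)
        for i in range(len(tokens) - k + 1):
            if tuple(tokens[i:i + k]) == parts:
                return True
    return False


def match_tweet(text: str, category: KeywordCategory | Iterable[str]) -> bool:
    """Whole-token, case-insensitive predicate: does ``text`` contain any
    surface form of ``category``?

    ``category`` may be a :class:`KeywordCategory` or a bare iterable of
    forms/terms (used for the self-identification list).
    """
    forms = category.forms if isinstance(category, KeywordCategory) else category
    return match_tokens(tokenize(text), forms)


def _read_lexicon_rows(rows: Iterable[Mapping[str, str]],
                       order: Sequence[str] | None = None) -> dict[str, KeywordCategory]:
    by_cat: dict[str, list[str]] = {}
    for row in rows:
        by_cat.setdefault(row["category"], []).append(row["form"].strip().lower())
    names = list(order) if order else list(by_cat)
    out = {}
    for name in names:
        forms = by_cat[name]
        if len(forms) != len(set(forms)):
            raise ValueError(f"duplicate forms in category {name!r}")
        out[name] = KeywordCategory(name=name, roots=(name,), forms=frozenset(forms))
    return out


def lexicon_from_csv(path) -> dict[str, KeywordCategory]:
    """Load a lexicon from a 2-column CSV (``category,form``)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_lexicon_rows(csv.DictReader(fh))


def lexicon_to_csv(lexicon: Mapping[str, KeywordCategory], path) -> None:
    """Write a lexicon to a 2-column CSV (``category,form``), forms sorted."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "form"])
        for cat in lexicon.values():
            for form in sorted(cat.forms):
                w.writerow([cat.name, form])


def _builtin(name: str, order: Sequence[str]) -> dict[str, KeywordCategory]:
    ref = resources.files("tweetlex.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return _read_lexicon_rows(csv.DictReader(fh), order=order)


def builtin_emotion_lexicon() -> dict[str, KeywordCategory]:
    """The three emotion categories (fear, anxiety, paranoia)."""
    return _builtin("emotion_lexicon.csv", EMOTION_CATEGORIES)


def builtin_ocd_lexicon() -> dict[str, KeywordCategory]:
    """The thirteen obsessive-compulsive behaviour categories."""
    return _builtin("ocd_lexicon.csv", OCD_CATEGORIES)


def builtin_asd_identification_terms() -> list[str]:
    """The 13 self-identification terms (lowercased; hashtags keep '#')."""
    ref = resources.files("tweetlex.data").joinpath("asd_terms.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return [row["term"] for row in csv.DictReader(fh)]
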