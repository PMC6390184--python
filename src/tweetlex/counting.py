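"""Per-user, per-category deduplicated tweet counting.

The unit of counting is the tweet, not the keyword occurrence: a tweet
containing "anxious" and "anxiety" contributes 1 to the anxiety category,
and a tweet containing "anxious" and "fear" contributes 1 to each of the two
categories. An *aggregate* over a category set counts distinct tweets that
match at least one member category, so a multi-category tweet contributes
exactly 1 to the aggregate.

``total_tweets`` for a user is the number of in-window tweets supplied,
matching or not (retweets included unless the caller filtered them out), as
that total is the denominator of the per-user proportion downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicons import KeywordCategory, tokenize, match_tokens
from .records import TweetRecord

__all__ = ["LexiconMatcher", "CategoryCountTable", "count_user_categories",
           "count_aggregate", "count_corpus"]


def _as_categories(categories) -> list[KeywordCategory]:
    if isinstance(categories, Mapping):
        return list(categories.values())
    return list(categories)


def _texts_of(tweets: Iterable) -> list[str]:
    return [t.text if isinstance(t, TweetRecord) else str(t) for t in tweets]


class LexiconMatcher:
    """Matches texts against a fixed set of categories in one pass.

    Builds a token -> categories index so a text is tokenized once regardless
    of how many categories are queried. Multi-word forms fall back to a
    contiguous-subsequence scan.
    """

    def __init__(self, categories) -> None:
        cats = _as_categories(categories)
        self.names: tuple[str, ...] = tuple(c.name for c in cats)
        self._index: dict[str, frozenset[int]] = {}
        self._multi: list[tuple[tuple[str, ...], int]] = []
        tok_to_cats: dict[str, set[int]] = {}
        for ci, cat in enumerate(cats):
            for form in cat.forms:
                parts = form.split()
                if len(parts) == 1:
                    tok_to_cats.setdefault(form, set()).add(ci)
                else:
                    self._multi.append((tuple(parts), ci))
        self._index = {t: frozenset(s) for t, s in tok_to_cats.items()}

    def match_text(self, text: str) -> frozenset[str]:
        """Names of the categories that ``text`` matches."""
        return frozenset(self.names[i] for i in self._match_ids(tokenize(text)))

    def _match_ids(self, tokens: Sequence[str]) -> set[int]:
        idx = self._index
        hit: set[int] = set()
        for tok in tokens:
            cats = idx.get(tok)
            if cats:
                hit |= cats
        for parts, ci in self._multi:
            if ci in hit:
                continue
            k = len(parts)
            for i in range(len(tokens) - k + 1):
                if tuple(tokens[i:i + k]) == parts:
                    hit.add(ci)
                    break
        return hit

    def match_matrix(self, texts: Sequence[str]) -> np.ndarray:
        """Boolean (n_texts, n_categories) match matrix.

        Tokenization is memoized over unique texts, which makes corpora with
        repeated texts (common in synthetic data) cheap; identical texts have
        identical match sets, so memoization cannot change any count.
        """
        codes, uniques = pd.factorize(np.asarray(texts, dtype=object))
        uniq = np.zeros((len(uniques), len(self.names)), dtype=bool)
        for ui, text in enumerate(uniques):
            for ci in self._match_ids(tokenize(text)):
                uniq[ui, ci] = True
        return uniq[codes]


@dataclass(frozen=True)
class CategoryCountTable:
    """Deduplicated per-user counts: ``counts`` is a DataFrame indexed by
    user_id with one column per category (and per aggregate, if requested);
    ``totals`` is the per-user total tweet count."""

    counts: pd.DataFrame
    totals: pd.Series

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: user_id, category, matched_tweets, total_tweets."""
        long = (self.counts.stack().rename("matched_tweets")
                .reset_index())
        long.columns = ["user_id", "category", "matched_tweets"]
        long["total_tweets"] = long["user_id"].map(self.totals).astype(int)
        return long

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def count_user_categories(tweets: Iterable, categories) -> tuple[dict[str, int], int]:
    """Counts of distinct matching tweets per category for one user's tweets.

    Returns ``(per_category_counts, total_tweets)``; a tweet contributes at
    most 1 to each category however many of its forms appear.
    """
    matcher = categories if isinstance(categories, LexiconMatcher) else LexiconMatcher(categories)
    counts = dict.fromkeys(matcher.names, 0)
    total = 0
    for text in _texts_of(tweets):
        total += 1
        for name in matcher.match_text(text):
            counts[name] += 1
    return counts, total


def count_aggregate(tweets: Iterable, category_set) -> int:
    """Distinct tweets matching >= 1 form from >= 1 category in the set."""
    matcher = (category_set if isinstance(category_set, LexiconMatcher)
               else LexiconMatcher(category_set))
    return sum(1 for text in _texts_of(tweets) if matcher.match_text(text))


def count_corpus(tweets: pd.DataFrame, categories,
                 aggregates: Mapping[str, Sequence[str]] | None = None,
                 user_ids: Sequence[str] | None = None) -> CategoryCountTable:
    """Count every user in a tweet DataFrame (columns ``user_id``, ``text``).

    ``aggregates`` maps an output column name to the member categories it
    unions (distinct-tweet semantics). ``user_ids`` fixes the set and order
    of users in the output; users with no tweets get all-zero rows.
    """
    matcher = categories if isinstance(categories, LexiconMatcher) else LexiconMatcher(categories)
    names = list(matcher.names)
    m = matcher.match_matrix(tweets["text"].tolist())
    per_tweet = pd.DataFrame(m, columns=names, index=tweets.index)
    if aggregates:
        for agg_name, members in aggregates.items():
            cols = [c for c in members]
            per_tweet[agg_name] = per_tweet[cols].any(axis=1)
    gb = per_tweet.groupby(tweets["user_id"].to_numpy())
    counts = gb.sum().astype(int)
    totals = gb.size().rename("total_tweets")
    if user_ids is not None:
        counts = counts.reindex(list(user_ids), fill_value=0)
        totals = totals.reindex(list(user_ids), fill_value=0)
    counts.index.name = "user_id"
    totals.index.name = "user_id"
    return CategoryCountTable(counts=counts, totals=totals)
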