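"""Deduplicated per-user category counting against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from tweetlex.counting import (LexiconMatcher, count_aggregate, count_corpus,
                               count_user_categories)
from tweetlex.lexicons import builtin_emotion_lexicon, builtin_ocd_lexicon

LEX = {**builtin_emotion_lexicon(), **builtin_ocd_lexicon()}
EMOTION = {k: LEX[k] for k in ("fear", "anxiety", "paranoia")}
FILLERS = ["lorem", "ipsum", "dolor", "amet", "tempor", "labore", "magna"]


def brute_force_counts(texts, categories):
    """Independent oracle: double loop over (tweet, form), whole-token."""
    counts = {}
    for name, cat in categories.items():
        n = 0
        for text in texts:
            toks = [t.strip("!.,?;:'\"()[]") for t in text.lower().split()]
            if any(form in toks for form in cat.forms):
                n += 1
        counts[name] = n
    return counts


class TestDedupRules:
    def test_multiple_forms_count_once(self):
        counts, total = count_user_categories(
            ["anxious about my anxiety"], EMOTION)
        assert counts["anxiety"] == 1 and total == 1

    def test_multi_category_tweet_counts_once_per_category(self):
        counts, _ = count_user_categories(["anxious and fearful"], EMOTION)
        assert counts["anxiety"] == 1 and counts["fear"] == 1

    def test_empty_input(self):
        counts, total = count_user_categories([], EMOTION)
        assert total == 0 and all(v == 0 for v in counts.values())

    def test_aggregate_dedups_across_categories(self):
        tweets = ["anxious and fearful"]
        agg = count_aggregate(tweets, EMOTION)
        counts, _ = count_user_categories(tweets, EMOTION)
        assert agg == 1 and sum(counts.values()) == 2

    def test_aggregate_disjoint_tweets(self):
        tweets = ["pure fear", "so anxious", "feeling paranoid"]
        assert count_aggregate(tweets, EMOTION) == 3

    def test_aggregate_no_match(self):
        assert count_aggregate(["lorem ipsum"], EMOTION) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_corpora_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vocab = FILLERS + [f for c in LEX.values() for f in sorted(c.forms)]
        texts = [" ".join(rng.choice(vocab, size=rng.integers(1, 9)))
                 for _ in range(rng.integers(1, 200))]
        expected = brute_force_counts(texts, LEX)
        counts, total = count_user_categories(texts, LEX)
        assert counts == expected and total == len(texts)
        # aggregate = distinct tweets matching any category
        agg_expected = sum(
            1 for text in texts
            if any(f in text.split() for c in LEX.values() for f in c.forms))
        assert count_aggregate(texts, LEX) == agg_expected

    def test_corpus_frame_matches_per_user(self):
        rng = np.random.default_rng(3)
        vocab = FILLERS + ["fear", "anxious", "counting"]
        rows = [{"user_id": f"u{rng.integers(0, 5)}",
                 "text": " ".join(rng.choice(vocab, size=4))}
                for _ in range(300)]
        df = pd.DataFrame(rows)
        table = count_corpus(df, LEX, aggregates={"any": list(LEX)})
        for uid, sub in df.groupby("user_id"):
            counts, total = count_user_categories(sub["text"].tolist(), LEX)
            assert table.totals[uid] == total
            for cat, v in counts.items():
                assert table.counts.loc[uid, cat] == v
            assert table.counts.loc[uid, "any"] == \
                count_aggregate(sub["text"].tolist(), LEX)


class TestInvariants:
    def test_count_bounded_by_total(self, small_corpus):
        table = count_corpus(small_corpus.tweets, LEX)
        assert (table.counts.le(table.totals, axis=0)).all().all()

    def test_aggregate_bounds(self):
        rng = np.random.default_rng(11)
        vocab = FILLERS + ["fear", "anxiety", "paranoid"]
        texts = [" ".join(rng.choice(vocab, size=3)) for _ in range(150)]
        counts, _ = count_user_categories(texts, EMOTION)
        agg = count_aggregate(texts, EMOTION)
        assert max(counts.values()) <= agg <= sum(counts.values())

    def test_monotone_in_tweets_and_forms(self):
        texts = ["fear itself", "lorem ipsum", "anxious day"]
        counts1, _ = count_user_categories(texts, EMOTION)
        counts2, _ = count_user_categories(texts + ["more fear"], EMOTION)
        assert all(counts2[c] >= counts1[c] for c in counts1)
        # widening a category's form set cannot lower its count
        from tweetlex.lexicons import KeywordCategory
        wider = {"fear": KeywordCategory(
            "fear", ("fear",), EMOTION["fear"].forms | frozenset(["lorem"]))}
        counts3, _ = count_user_categories(texts, wider)
        assert counts3["fear"] >= counts1["fear"]

    def test_long_format_round_trip(self, tmp_path):
        df = pd.DataFrame({"user_id": ["u1", "u1", "u2"],
                           "text": ["fear", "lorem", "anxious anxiety"]})
        table = count_corpus(df, EMOTION)
        out = tmp_path / "counts.csv"
        table.to_csv(out)
        back = pd.read_csv(out)
        assert set(back.columns) == {"user_id", "category", "matched_tweets",
                                     "total_tweets"}
        row = back[(back.user_id == "u2") & (back.category == "anxiety")]
        assert row.matched_tweets.item() == 1 and row.total_tweets.item() == 1
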