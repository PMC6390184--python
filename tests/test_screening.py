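"""Candidate flagging, adjudication, account filtering, control sampling."""

import pandas as pd
import pytest

from tweetlex.lexicons import builtin_asd_identification_terms
from tweetlex.records import AccountStatus, FilterReason, UserRecord
from tweetlex.screening import (AdjudicationPendingError, CoderLabel,
                                adjudicate, filter_accounts, flag_candidates,
                                sample_controls, screen_cohorts, bot_heuristic)

TERMS = builtin_asd_identification_terms()


def _user(uid, profile="", status=AccountStatus.ACTIVE, bot=False):
    return UserRecord(user_id=uid, profile_text=profile,
                      account_status=status, bot_or_spam=bot)


class TestFlagCandidates:
    def test_profile_hashtag_flags(self):
        users = [_user("u1", profile="parent and #ActuallyAutistic advocate")]
        assert flag_candidates(pd.DataFrame({"user_id": [], "text": []}),
                               users, TERMS) == {"u1"}

    def test_tweet_keyword_flags(self):
        tweets = pd.DataFrame({"user_id": ["u2"],
                               "text": ["autism awareness walk"]})
        assert flag_candidates(tweets, [_user("u2")], TERMS) == {"u2"}

    def test_clean_user_not_flagged(self):
        tweets = pd.DataFrame({"user_id": ["u3"], "text": ["nice weather"]})
        assert flag_candidates(tweets, [_user("u3")], TERMS) == set()

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            flag_candidates(pd.DataFrame({"user_id": [], "text": []}),
                            [], [])


class TestAdjudicate:
    def test_agreement(self):
        labs = [CoderLabel("u", "coder1", "asd"), CoderLabel("u", "coder2", "asd")]
        assert adjudicate(labs) == "asd"

    def test_agreement_not_asd(self):
        labs = [CoderLabel("u", "coder1", "not_asd"),
                CoderLabel("u", "coder2", "not_asd")]
        assert adjudicate(labs) == "not_asd"

    def test_tie_break(self):
        labs = [CoderLabel("u", "coder1", "asd"),
                CoderLabel("u", "coder2", "not_asd"),
                CoderLabel("u", "coder3", "asd")]
        assert adjudicate(labs) == "asd"

    def test_symmetric_in_first_two_coders(self):
        a = [CoderLabel("u", "coder1", "asd"),
             CoderLabel("u", "coder2", "not_asd"),
             CoderLabel("u", "coder3", "not_asd")]
        b = [CoderLabel("u", "coder1", "not_asd"),
             CoderLabel("u", "coder2", "asd"),
             CoderLabel("u", "coder3", "not_asd")]
        assert adjudicate(a) == adjudicate(b)

    def test_pending_when_no_tiebreak(self):
        labs = [CoderLabel("u", "coder1", "asd"),
                CoderLabel("u", "coder2", "not_asd")]
        with pytest.raises(AdjudicationPendingError):
            adjudicate(labs)


class TestFilterAccounts:
    def test_reasons(self):
        users = [_user("ok"), _user("p", status=AccountStatus.PRIVATE),
                 _user("b", bot=True),
                 _user("bb", status=AccountStatus.BANNED, bot=True)]
        kept, removed = filter_accounts(users)
        assert kept == {"ok"}
        assert removed["p"] == FilterReason.PRIVATE
        assert removed["b"] == FilterReason.BOT_SPAM
        # bot flag takes precedence over status
        assert removed["bb"] == FilterReason.BOT_SPAM

    def test_idempotent(self):
        users = [_user("ok"), _user("d", status=AccountStatus.DELETED)]
        kept, _ = filter_accounts(users)
        kept2, removed2 = filter_accounts([u for u in users
                                           if u.user_id in kept])
        assert kept2 == kept and not removed2


class TestSampleControls:
    def test_exhaustive_pool(self):
        pool = [f"u{i}" for i in range(5)]
        assert sample_controls(pool, 5, set(), seed=3) == set(pool)

    def test_deterministic(self):
        pool = [f"u{i}" for i in range(50)]
        s1 = sample_controls(pool, 10, {"u0"}, seed=42)
        s2 = sample_controls(pool, 10, {"u0"}, seed=42)
        assert s1 == s2 and len(s1) == 10 and "u0" not in s1

    def test_undersized_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_controls(["u1"], 2, set(), seed=0)


def test_bot_heuristic_flags_extremes():
    tweets = pd.DataFrame({
        "user_id": ["spam"] * 400 + ["dup"] * 10 + ["ok"] * 10,
        "text": [f"t{i}" for i in range(400)] + ["same"] * 10
        + [f"u{i}" for i in range(10)],
    })
    flagged = bot_heuristic(tweets, n_days=2, max_tweets_per_day=100,
                            max_duplicate_fraction=0.5)
    assert flagged == {"spam", "dup"}


class TestScreenCohorts:
    def test_synthetic_fixture_sizes_and_conservation(self, small_corpus):
        res = screen_cohorts(small_corpus.users, small_corpus.tweets, TERMS,
                             small_corpus.coder_labels, n_controls=30, seed=1)
        truth = small_corpus.truth["expected_survivors"]
        assert len(res.final_asd) == truth["asd"]
        assert len(res.final_control) == truth["control"]
        assert res.final_asd <= res.adjudicated_asd <= res.candidates
        assert not (res.final_asd & res.final_control)
        sc = res.stage_counts
        assert sc["adjudicated_asd"] == sc["final_asd"] + sc["asd_filtered"]
        assert sc["controls_sampled"] == (sc["final_control"]
                                          + sc["controls_filtered"])

    def test_not_asd_candidates_never_controls(self):
        users = [_user(f"u{i}") for i in range(6)]
        tweets = pd.DataFrame({
            "user_id": ["u0", "u1"],
            "text": ["I have aspergers", "autism awareness day"]})
        labels = [CoderLabel("u0", "coder1", "asd"),
                  CoderLabel("u0", "coder2", "asd"),
                  CoderLabel("u1", "coder1", "not_asd"),
                  CoderLabel("u1", "coder2", "not_asd")]
        res = screen_cohorts(users, tweets, TERMS, labels,
                             n_controls=4, seed=0)
        assert res.final_asd == {"u0"}
        assert "u1" not in res.final_control
        assert res.final_control == {"u2", "u3", "u4", "u5"}
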