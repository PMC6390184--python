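"""Local-time conversion, 6-hour binning, and the timing tables."""

from datetime import datetime, time, timezone

import numpy as np
import pandas as pd
import pytest

from tweetlex.records import TweetRecord
from tweetlex.timing import (INTERVALS, bin_interval, local_time,
                             timezone_availability, timing_comparison)


def _tweet(uid, hour_utc, offset, tid="t0"):
    return TweetRecord(tweet_id=tid, user_id=uid, text="x",
                       created_at=datetime(2015, 6, 1, hour_utc,
                                           tzinfo=timezone.utc),
                       utc_offset_s=offset)


class TestLocalTime:
    def test_offset_shift(self):
        t = _tweet("u", 18, -18000)
        assert local_time(t).time() == time(13, 0)

    def test_absent_offset(self):
        assert local_time(_tweet("u", 18, None)) is None

    def test_wraps_to_previous_day(self):
        t = _tweet("u", 1, -7200)
        lt = local_time(t)
        assert lt.time() == time(23, 0)
        assert lt.date().day == 31  # previous calendar day


class TestBinInterval:
    @pytest.mark.parametrize("t,expected", [
        (time(0, 0), "00:00-05:59"),
        (time(5, 59, 59), "00:00-05:59"),
        (time(6, 0), "06:00-11:59"),
        (time(13, 45), "12:00-17:59"),
        (time(23, 59, 59), "18:00-23:59"),
    ])
    def test_boundaries(self, t, expected):
        assert bin_interval(t) == expected


class TestTimingComparison:
    def test_all_in_one_bin(self):
        tweets = [_tweet("a1", 13, 0, f"t{i}") for i in range(5)] + \
                 [_tweet("c1", 13, 0, f"s{i}") for i in range(7)]
        groups = {"a1": "asd", "c1": "control"}
        table, chis = timing_comparison(tweets, groups)
        third = table[table.interval == "12:00-17:59"]
        assert (third.proportion == 1.0).all()
        assert chis["12:00-17:59"].chi2 == 0.0

    def test_conservation_and_instant_invariance(self):
        # same instant expressed via two (UTC, offset) pairs -> same bin
        a = _tweet("a1", 18, -18000)          # 13:00 local
        b = TweetRecord(tweet_id="t1", user_id="a1", text="x",
                        created_at=datetime(2015, 6, 1, 9, tzinfo=timezone.utc),
                        utc_offset_s=14400)   # also 13:00 local
        tweets = [a, b, _tweet("c1", 2, 0, "t2")]
        table, _ = timing_comparison(tweets, {"a1": "asd", "c1": "control"})
        asd = table[table.group == "asd"]
        assert asd[asd.interval == "12:00-17:59"]["count"].item() == 2
        for g in ("asd", "control"):
            sub = table[table.group == g]
            assert sub["count"].sum() == {"asd": 2, "control": 1}[g]
            assert sub["proportion"].sum() == pytest.approx(1.0)

    def test_offsetless_tweets_excluded(self):
        tweets = [_tweet("a1", 13, 0, "t0"), _tweet("a1", 13, None, "t1"),
                  _tweet("c1", 13, 0, "t2")]
        table, _ = timing_comparison(tweets, {"a1": "asd", "c1": "control"})
        assert table[table.group == "asd"]["count"].sum() == 1

    def test_group_without_offsets_rejected(self):
        tweets = [_tweet("a1", 13, 0, "t0"), _tweet("c1", 13, None, "t1")]
        with pytest.raises(ValueError, match="zero offset-bearing"):
            timing_comparison(tweets, {"a1": "asd", "c1": "control"})

    def test_proportions_invariant_to_duplication(self):
        rng = np.random.default_rng(5)
        tweets = pd.DataFrame({
            "user_id": np.where(rng.random(200) < 0.5, "a1", "c1"),
            "created_at_s": rng.integers(1.4e9, 1.45e9, 200),
            "utc_offset_s": rng.choice([-18000.0, 0.0], 200),
        })
        groups = {"a1": "asd", "c1": "control"}
        t1, _ = timing_comparison(tweets, groups)
        t2, _ = timing_comparison(pd.concat([tweets, tweets]), groups)
        assert np.allclose(t1.proportion.to_numpy(), t2.proportion.to_numpy())


class TestTimezoneAvailability:
    def test_published_counts(self):
        groups = {f"a{i}": "asd" for i in range(152)}
        groups.update({f"c{i}": "control" for i in range(182)})
        rows = [{"user_id": f"a{i}", "utc_offset_s": 0.0} for i in range(111)]
        rows += [{"user_id": f"c{i}", "utc_offset_s": 0.0} for i in range(120)]
        tweets = pd.DataFrame(rows).assign(created_at_s=1.4e9)
        res = timezone_availability(groups, tweets)
        assert res.with_offset == {"asd": 111, "control": 120}
        assert res.without_offset == {"asd": 41, "control": 62}
        assert res.overall_fraction == pytest.approx(231 / 334)
        assert round(res.chi2.chi2, 1) == 2.0
        assert res.chi2.p == pytest.approx(0.16, abs=0.01)

    def test_all_users_with_offset_degenerate(self):
        groups = {"a1": "asd", "c1": "control"}
        tweets = pd.DataFrame({"user_id": ["a1", "c1"],
                               "utc_offset_s": [0.0, 0.0],
                               "created_at_s": [1.4e9, 1.4e9]})
        with pytest.raises(ValueError, match="margin"):
            timezone_availability(groups, tweets)
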