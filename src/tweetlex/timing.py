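"""Time-of-day posting analysis.

Tweets are converted to the author's local clock time by adding the
account's UTC offset to the UTC timestamp; tweets without offset metadata
are excluded. Local clock times fall into four 6-hour intervals
(00:00-05:59, 06:00-11:59, 12:00-17:59, 18:00-23:59, closed-open at second
resolution) and each group's interval proportions are tabulated. Each
interval is compared between groups with a tweet-level 2x2 chi-square
(in-interval vs out-of-interval, by group).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .records import TweetRecord, UserRecord
from .stats import ChiSquareResult, chi_square_2x2

__all__ = ["INTERVALS", "local_time", "bin_interval", "timing_comparison",
           "timezone_availability", "TimezoneAvailability"]

#: The four local-clock intervals, in order.
INTERVALS = ("00:00-05:59", "06:00-11:59", "12:00-17:59", "18:00-23:59")

_SECONDS_PER_BIN = 6 * 3600


def local_time(tweet: TweetRecord) -> Optional[datetime]:
    """Local timestamp of a tweet, or ``None`` when no offset is available."""
    if tweet.utc_offset_s is None:
        return None
    return tweet.created_at + timedelta(seconds=tweet.utc_offset_s)


def bin_interval(t) -> str:
    """Map a local clock time (``datetime.time`` or datetime) to its interval."""
    if isinstance(t, datetime):
        t = t.time()
    sod = t.hour * 3600 + t.minute * 60 + t.second
    return INTERVALS[sod // _SECONDS_PER_BIN]


def _tweets_frame(tweets) -> pd.DataFrame:
    if isinstance(tweets, pd.DataFrame):
        return tweets
    rows = [(t.user_id,
             int(t.created_at.timestamp()),
             t.utc_offset_s)
            for t in tweets]
    return pd.DataFrame(rows, columns=["user_id", "created_at_s", "utc_offset_s"])


def _epoch_seconds(df: pd.DataFrame) -> np.ndarray:
    if "created_at_s" in df.columns:
        return df["created_at_s"].to_numpy(dtype=np.int64)
    ts = pd.to_datetime(df["created_at"], utc=True)
    return (ts.astype("int64") // 10**9).to_numpy()


def timing_comparison(tweets, groups: Mapping[str, str]
                      ) -> tuple[pd.DataFrame, dict[str, ChiSquareResult]]:
    """Per-group interval counts/proportions and per-interval chi-squares.

    ``tweets`` is a DataFrame (columns ``user_id``, ``utc_offset_s`` and
    either epoch-second ``created_at_s`` or datetime ``created_at``) or an
    iterable of :class:`TweetRecord`. ``groups`` maps user_id -> group name.
    Only offset-bearing tweets of mapped users are tabulated; every group
    must contribute at least one such tweet.
    """
    df = _tweets_frame(tweets)
    grp = df["user_id"].map(dict(groups))
    offset = pd.to_numeric(df["utc_offset_s"], errors="coerce")
    mask = grp.notna() & offset.notna()
    if not mask.any():
        raise ValueError("no offset-bearing tweets for any mapped user")
    epoch = _epoch_seconds(df)[mask.to_numpy()]
    local_sod = (epoch + offset[mask].to_numpy(dtype=np.int64)) % 86400
    bins = local_sod // _SECONDS_PER_BIN
    gvals = grp[mask].to_numpy()

    rows = []
    counts_by_group: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(groups.values()):
        sel = gvals == g
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"group {g!r} has zero offset-bearing tweets")
        c = np.bincount(bins[sel].astype(int), minlength=4)
        counts_by_group[g] = c
        for i, interval in enumerate(INTERVALS):
            rows.append({"group": g, "interval": interval,
                         "count": int(c[i]), "proportion": c[i] / n})
    table = pd.DataFrame(rows)

    gnames = list(counts_by_group)
    chis: dict[str, ChiSquareResult] = {}
    if len(gnames) == 2:
        c1, c2 = counts_by_group[gnames[0]], counts_by_group[gnames[1]]
        for i, interval in enumerate(INTERVALS):
            a, b = int(c1[i]), int(c1.sum() - c1[i])
            c, d = int(c2[i]), int(c2.sum() - c2[i])
            if a + c == 0 or b + d == 0:
                # no between-group contrast exists for this interval
                chis[interval] = ChiSquareResult(chi2=0.0, df=1, p=1.0)
            else:
                chis[interval] = chi_square_2x2(a, b, c, d)
    return table, chis


@dataclass(frozen=True)
class TimezoneAvailability:
    """User-level offset availability by group, with the 2x2 chi-square."""

    with_offset: dict[str, int]
    without_offset: dict[str, int]
    overall_fraction: float
    chi2: ChiSquareResult


def timezone_availability(users: Iterable[UserRecord] | Mapping[str, str],
                          tweets) -> TimezoneAvailability:
    """Fraction of users with >= 1 offset-bearing tweet, compared by group.

    ``users`` is either UserRecord objects (group read from the record) or a
    user_id -> group mapping. Exactly two groups must be present.
    """
    if isinstance(users, Mapping):
        groups = dict(users)
    else:
        groups = {u.user_id: (u.group.value if hasattr(u.group, "value") else str(u.group))
                  for u in users}
    df = _tweets_frame(tweets)
    offset = pd.to_numeric(df["utc_offset_s"], errors="coerce")
    has = set(df.loc[offset.notna(), "user_id"])
    gnames = list(dict.fromkeys(groups.values()))
    if len(gnames) != 2:
        raise ValueError(f"expected exactly 2 groups, got {gnames}")
    w = {g: 0 for g in gnames}
    wo = {g: 0 for g in gnames}
    for uid, g in groups.items():
        (w if uid in has else wo)[g] += 1
    total = sum(w.values()) + sum(wo.values())
    overall = sum(w.values()) / total if total else 0.0
    g1, g2 = gnames
    chi = chi_square_2x2(w[g1], wo[g1], w[g2], wo[g2])
    return TimezoneAvailability(with_offset=w, without_offset=wo,
                                overall_fraction=overall, chi2=chi)
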