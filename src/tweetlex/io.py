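"""Readers and writers for the pipeline's file formats.

Tweets travel as JSON-lines. Two dialects are accepted: the historical
Twitter API v1.1 shape (``id_str``, ``user.id_str``, ``text``,
``created_at`` in the classic ``"%a %b %d %H:%M:%S %z %Y"`` form,
``user.utc_offset``, with retweets signalled by a ``retweeted_status`` key)
and a flat dialect (``tweet_id``, ``user_id``, ``text``, ISO-8601
``created_at``, ``utc_offset_s``, ``is_retweet``) which is also what the
writer emits. Unknown keys are ignored. Users and coder labels are plain
CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .records import StudyWindow, TweetRecord, UserRecord, Group, AccountStatus
from .screening import CoderLabel
from .stats import WelchResult

__all__ = ["TweetParseError", "TweetReadResult", "read_tweets", "write_tweets",
           "read_users_csv", "write_users_csv", "read_coder_labels_csv",
           "write_coder_labels_csv", "GroupComparison", "write_comparison_csv",
           "read_comparison_csv", "records_to_frame", "frame_to_records"]

_TWITTER_TS = "%a %b %d %H:%M:%S %z %Y"
_REQUIRED = ("tweet_id", "user_id", "text", "created_at")


class TweetParseError(ValueError):
    """A JSONL line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _parse_timestamp(s: str) -> datetime:
    try:
        return datetime.strptime(s, _TWITTER_TS)
    except ValueError:
        pass
    ts = datetime.fromisoformat(s.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _flatten(obj: dict) -> dict:
    """Normalize either accepted dialect to flat field names."""
    if "tweet_id" in obj or "user_id" in obj:
        return obj
    user = obj.get("user") or {}
    return {
        "tweet_id": obj.get("id_str") or (str(obj["id"]) if "id" in obj else None),
        "user_id": user.get("id_str") or (str(user["id"]) if "id" in user else None),
        "text": obj.get("text"),
        "created_at": obj.get("created_at"),
        "utc_offset_s": user.get("utc_offset"),
        "is_retweet": "retweeted_status" in obj,
    }


@dataclass
class TweetReadResult:
    """Parsed in-window records plus read bookkeeping."""

    records: list[TweetRecord]
    n_lines: int
    n_out_of_window: int

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_tweets(path, window: StudyWindow) -> TweetReadResult:
    """Read a JSONL tweet file, keeping records dated inside ``window``.

    Raises :class:`TweetParseError` (naming the line) for unparsable JSON or
    a missing required field; out-of-window records are dropped and counted.
    """
    records: list[TweetRecord] = []
    n_lines = out = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            try:
                obj = _flatten(json.loads(line))
            except json.JSONDecodeError as e:
                raise TweetParseError(lineno, f"invalid JSON ({e.msg})") from None
            missing = [k for k in _REQUIRED if obj.get(k) is None]
            if missing:
                raise TweetParseError(lineno, f"missing required field(s) {missing}")
            try:
                ts = _parse_timestamp(obj["created_at"])
            except ValueError:
                raise TweetParseError(
                    lineno, f"unparsable created_at {obj['created_at']!r}") from None
            if not window.contains(ts):
                out += 1
                continue
            off = obj.get("utc_offset_s")
            records.append(TweetRecord(
                tweet_id=str(obj["tweet_id"]), user_id=str(obj["user_id"]),
                text=str(obj["text"]), created_at=ts,
                utc_offset_s=None if off is None else int(off),
                is_retweet=bool(obj.get("is_retweet", False))))
    return TweetReadResult(records=records, n_lines=n_lines, n_out_of_window=out)


def write_tweets(tweets, path) -> None:
    """Write tweets (records or a DataFrame) as flat-dialect JSONL."""
    if isinstance(tweets, pd.DataFrame):
        tweets = frame_to_records(tweets)
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            obj = {
                "tweet_id": t.tweet_id,
                "user_id": t.user_id,
                "text": t.text,
                "created_at": t.created_at.astimezone(timezone.utc).isoformat(),
                "utc_offset_s": t.utc_offset_s,
                "is_retweet": t.is_retweet,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def records_to_frame(records: Iterable[TweetRecord]) -> pd.DataFrame:
    """Column-oriented view of tweet records used by the corpus-level stages."""
    rows = [(t.tweet_id, t.user_id, t.text,
             int(t.created_at.timestamp()),
             np.nan if t.utc_offset_s is None else float(t.utc_offset_s),
             t.is_retweet) for t in records]
    return pd.DataFrame(rows, columns=["tweet_id", "user_id", "text",
                                       "created_at_s", "utc_offset_s",
                                       "is_retweet"])


def frame_to_records(df: pd.DataFrame) -> list[TweetRecord]:
    out = []
    for row in df.itertuples(index=False):
        off = getattr(row, "utc_offset_s", None)
        off = None if off is None or (isinstance(off, float) and np.isnan(off)) else int(off)
        out.append(TweetRecord(
            tweet_id=str(row.tweet_id), user_id=str(row.user_id),
            text=str(row.text),
            created_at=datetime.fromtimestamp(int(row.created_at_s), tz=timezone.utc),
            utc_offset_s=off, is_retweet=bool(row.is_retweet)))
    return out


_USER_COLS = ["user_id", "profile_text", "statuses_count", "friends_count",
              "followers_count", "favorites_count", "account_status",
              "bot_or_spam"]


def read_users_csv(path) -> list[UserRecord]:
    users = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            users.append(UserRecord(
                user_id=row["user_id"], profile_text=row.get("profile_text", ""),
                statuses_count=int(row["statuses_count"]),
                friends_count=int(row["friends_count"]),
                followers_count=int(row["followers_count"]),
                favorites_count=int(row["favorites_count"]),
                account_status=AccountStatus(row["account_status"]),
                bot_or_spam=row["bot_or_spam"].strip().lower() in ("1", "true", "yes"),
            ))
    return users


def write_users_csv(users: Iterable[UserRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_USER_COLS)
        for u in users:
            w.writerow([u.user_id, u.profile_text, u.statuses_count,
                        u.friends_count, u.followers_count, u.favorites_count,
                        u.account_status.value, str(u.bot_or_spam).lower()])


def read_coder_labels_csv(path) -> list[CoderLabel]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [CoderLabel(row["user_id"], row["coder_id"], row["label"])
                for row in csv.DictReader(fh)]


def write_coder_labels_csv(labels: Iterable[CoderLabel], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["user_id", "coder_id", "label"])
        for lab in labels:
            w.writerow([lab.user_id, lab.coder_id, lab.label])


@dataclass(frozen=True)
class GroupComparison:
    """One category's between-group comparison of mean-of-proportions."""

    category: str
    asd_mean: float
    asd_sd: float
    control_mean: float
    control_sd: float
    welch: WelchResult

    @property
    def t(self) -> float:
        return self.welch.t

    @property
    def df(self) -> float:
        return self.welch.df

    @property
    def p(self) -> float:
        return self.welch.p_two_tailed


_CMP_COLS = ["category", "asd_mean", "asd_sd", "control_mean", "control_sd",
             "t", "df", "p"]


def write_comparison_csv(table: Iterable[GroupComparison], path) -> None:
    """Write comparison rows; floats use shortest round-trip representation."""
    rows = list(table)
    if not rows:
        raise ValueError("empty comparison table")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CMP_COLS)
        for r in rows:
            w.writerow([r.category, repr(r.asd_mean), repr(r.asd_sd),
                        repr(r.control_mean), repr(r.control_sd),
                        repr(r.t), repr(r.df), repr(r.p)])


def read_comparison_csv(path) -> list[GroupComparison]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(GroupComparison(
                category=row["category"],
                asd_mean=float(row["asd_mean"]), asd_sd=float(row["asd_sd"]),
                control_mean=float(row["control_mean"]),
                control_sd=float(row["control_sd"]),
                welch=WelchResult(t=float(row["t"]), df=float(row["df"]),
                                  p_two_tailed=float(row["p"]))))
    return out
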