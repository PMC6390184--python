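"""Core record types shared by every stage of the pipeline.

A corpus is a pair of collections: tweet records (one per post) and user
records (one per account). Records are plain frozen dataclasses; the
corpus-level functions in :mod:`tweetlex.counting` and :mod:`tweetlex.timing`
also accept pandas DataFrames with the same column names, which is how the
pipeline moves large corpora around.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Optional

#: Valid range of a UTC offset in seconds (UTC-12:00 .. UTC+14:00).
UTC_OFFSET_RANGE = (-43200, 50400)


class Group(str, enum.Enum):
    """Study-group label of a user."""

    ASD = "asd"
    CONTROL = "control"
    UNASSIGNED = "unassigned"


class AccountStatus(str, enum.Enum):
    """Accessibility of an account at collection time."""

    ACTIVE = "active"
    PRIVATE = "private"
    DELETED = "deleted"
    DEACTIVATED = "deactivated"
    BANNED = "banned"


class FilterReason(str, enum.Enum):
    """Why a user was removed during account screening."""

    BOT_SPAM = "bot_spam"
    PRIVATE = "private"
    DELETED = "deleted"
    DEACTIVATED = "deactivated"
    BANNED = "banned"


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One post: author, text, UTC timestamp, optional UTC offset, retweet flag."""

    tweet_id: str
    user_id: str
    text: str
    created_at: datetime  # tz-aware UTC, second resolution
    utc_offset_s: Optional[int] = None
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if self.created_at.tzinfo is None:
            object.__setattr__(
                self, "created_at", self.created_at.replace(tzinfo=timezone.utc)
            )
        if self.utc_offset_s is not None:
            lo, hi = UTC_OFFSET_RANGE
            if not lo <= self.utc_offset_s <= hi:
                raise ValueError(
                    f"utc_offset_s {self.utc_offset_s} outside [{lo}, {hi}]"
                )


@dataclass(frozen=True, slots=True)
class UserRecord:
    """One account: profile text, group label, activity metadata, status flags."""

    user_id: str
    profile_text: str = ""
    group: Group = Group.UNASSIGNED
    statuses_count: int = 0
    friends_count: int = 0
    followers_count: int = 0
    favorites_count: int = 0
    account_status: AccountStatus = AccountStatus.ACTIVE
    bot_or_spam: bool = False

    def __post_init__(self) -> None:
        for name in ("statuses_count", "friends_count", "followers_count",
                     "favorites_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True, slots=True)
class StudyWindow:
    """Calendar collection window, inclusive of both endpoint dates.

    ``n_days`` is the difference ``end_date - start_date`` in days, the
    convention under which the default five-year window spans 1946 days.
    """

    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date precedes start_date")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days

    def contains(self, ts: datetime) -> bool:
        """True if the UTC date of ``ts`` lies inside the window (inclusive)."""
        d = ts.astimezone(timezone.utc).date() if ts.tzinfo else ts.date()
        return self.start_date <= d <= self.end_date


#: The study window used throughout: 2012-03-22 .. 2017-07-20 (1946 days).
DEFAULT_WINDOW = StudyWindow(date(2012, 3, 22), date(2017, 7, 20))
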