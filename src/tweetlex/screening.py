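"""Cohort assembly: candidate flagging, coder adjudication, account filtering,
and control sampling.

Candidate case users are flagged by self-identification keywords found in
their tweets or profile text. Two independent coders label each candidate;
agreement decides, and a third coder breaks ties. Bots, spam accounts and
inaccessible accounts (private, deleted, deactivated, banned) are filtered
from both groups. Controls are a uniform random sample of unflagged users,
drawn before account filtering (so the final control group can be smaller
than the sampled one, as in the original cohort construction).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .counting import LexiconMatcher
from .lexicons import KeywordCategory, match_tweet
from .records import AccountStatus, FilterReason, UserRecord

__all__ = ["CoderLabel", "ScreeningResult", "AdjudicationPendingError",
           "flag_candidates", "adjudicate", "filter_accounts",
           "sample_controls", "screen_cohorts", "bot_heuristic"]


class AdjudicationPendingError(ValueError):
    """Coders disagree and no tie-break label is available."""


@dataclass(frozen=True)
class CoderLabel:
    """One coder's ASD / not-ASD call for one user."""

    user_id: str
    coder_id: str  # "coder1" | "coder2" | "coder3"
    label: str     # "asd" | "not_asd"


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the full screen with per-stage bookkeeping."""

    candidates: frozenset[str]
    adjudicated_asd: frozenset[str]
    filtered_out: dict[str, FilterReason]
    final_asd: frozenset[str]
    final_control: frozenset[str]
    stage_counts: dict[str, int] = field(default_factory=dict)


def _term_matcher(terms: Sequence[str]) -> LexiconMatcher:
    cat = KeywordCategory(name="_terms", roots=tuple(terms),
                          forms=frozenset(t.lower() for t in terms))
    return LexiconMatcher([cat])


def flag_candidates(tweets, users: Iterable[UserRecord],
                    terms: Sequence[str]) -> set[str]:
    """Users whose tweets or profile text match >= 1 self-identification term."""
    if not terms:
        raise ValueError("terms must be non-empty")
    matcher = _term_matcher(terms)
    flagged: set[str] = set()
    for u in users:
        if u.profile_text and matcher.match_text(u.profile_text):
            flagged.add(u.user_id)
    if isinstance(tweets, pd.DataFrame):
        m = matcher.match_matrix(tweets["text"].tolist())[:, 0]
        flagged |= set(tweets.loc[m, "user_id"])
    else:
        for t in tweets:
            if t.user_id not in flagged and matcher.match_text(t.text):
                flagged.add(t.user_id)
    return flagged


def adjudicate(labels: Iterable[CoderLabel]) -> str:
    """Resolve one user's coder labels: agreement decides, coder3 breaks ties."""
    by_coder = {}
    for lab in labels:
        if lab.coder_id in by_coder:
            raise ValueError(f"duplicate label from {lab.coder_id}")
        by_coder[lab.coder_id] = lab.label
    try:
        l1, l2 = by_coder["coder1"], by_coder["coder2"]
    except KeyError as e:
        raise ValueError(f"missing label from {e.args[0]}") from None
    if l1 == l2:
        return l1
    if "coder3" not in by_coder:
        raise AdjudicationPendingError(
            "coders disagree and no tie-break label is present")
    return by_coder["coder3"]


_STATUS_REASON = {
    AccountStatus.PRIVATE: FilterReason.PRIVATE,
    AccountStatus.DELETED: FilterReason.DELETED,
    AccountStatus.DEACTIVATED: FilterReason.DEACTIVATED,
    AccountStatus.BANNED: FilterReason.BANNED,
}


def filter_accounts(users: Iterable[UserRecord]
                    ) -> tuple[set[str], dict[str, FilterReason]]:
    """Split users into kept ids and removed ids with the removal reason.

    Bot/spam flags take precedence over inaccessibility when both apply.
    Idempotent: filtering the kept set again removes nobody.
    """
    kept: set[str] = set()
    removed: dict[str, FilterReason] = {}
    for u in users:
        if u.bot_or_spam:
            removed[u.user_id] = FilterReason.BOT_SPAM
        elif u.account_status != AccountStatus.ACTIVE:
            removed[u.user_id] = _STATUS_REASON[AccountStatus(u.account_status)]
        else:
            kept.add(u.user_id)
    return kept, removed


def sample_controls(users: Iterable[UserRecord] | Iterable[str], n: int,
                    excluded: set[str], seed: int) -> set[str]:
    """Uniform sample of ``n`` eligible user ids without replacement.

    Deterministic given ``seed``; the pool is every supplied user not in
    ``excluded``.
    """
    ids = sorted({u if isinstance(u, str) else u.user_id for u in users} - set(excluded))
    if len(ids) < n:
        raise ValueError(f"eligible pool has {len(ids)} users, need {n}")
    rng = np.random.default_rng(seed)
    return set(rng.choice(ids, size=n, replace=False))


def bot_heuristic(tweets: pd.DataFrame, n_days: int,
                  max_tweets_per_day: float = 100.0,
                  max_duplicate_fraction: float = 0.5) -> set[str]:
    """Optional helper flagging automated-looking accounts.

    Flags a user when their posting rate exceeds ``max_tweets_per_day`` over
    the window or when more than ``max_duplicate_fraction`` of their tweets
    share an already-seen text. Off by default in the pipeline: on real data
    the input ``bot_or_spam`` flag is authoritative.
    """
    flagged: set[str] = set()
    for uid, sub in tweets.groupby("user_id"):
        if len(sub) / max(n_days, 1) > max_tweets_per_day:
            flagged.add(uid)
            continue
        dup = 1.0 - sub["text"].nunique() / len(sub)
        if dup > max_duplicate_fraction:
            flagged.add(uid)
    return flagged


def screen_cohorts(users: Iterable[UserRecord], tweets,
                   terms: Sequence[str],
                   coder_labels: Iterable[CoderLabel],
                   n_controls: int, seed: int) -> ScreeningResult:
    """Run the full screen: flag -> adjudicate -> sample controls -> filter.

    Candidates adjudicated not-ASD are excluded from the control pool
    entirely. Controls are sampled before account filtering; account
    filtering then removes bots/spam and inaccessible accounts from both
    groups.
    """
    users = list(users)
    candidates = flag_candidates(tweets, users, terms)

    labels_by_user: dict[str, list[CoderLabel]] = {}
    for lab in coder_labels:
        labels_by_user.setdefault(lab.user_id, []).append(lab)
    adjudicated = {uid for uid in candidates
                   if adjudicate(labels_by_user.get(uid, [])) == "asd"}

    sampled_controls = sample_controls(users, n_controls, excluded=candidates,
                                       seed=seed)
    kept, removed = filter_accounts(users)
    final_asd = adjudicated & kept
    final_control = sampled_controls & kept

    reason_counts = Counter(r.value for u, r in removed.items()
                            if u in adjudicated or u in sampled_controls)
    stage_counts = {
        "users_in": len(users),
        "candidates_flagged": len(candidates),
        "adjudicated_asd": len(adjudicated),
        "adjudicated_not_asd": len(candidates) - len(adjudicated),
        "controls_sampled": len(sampled_controls),
        "asd_filtered": len(adjudicated) - len(final_asd),
        "controls_filtered": len(sampled_controls) - len(final_control),
        "final_asd": len(final_asd),
        "final_control": len(final_control),
        **{f"filtered_{k}": v for k, v in sorted(reason_counts.items())},
    }
    return ScreeningResult(
        candidates=frozenset(candidates),
        adjudicated_asd=frozenset(adjudicated),
        filtered_out={u: r for u, r in removed.items()
                      if u in adjudicated or u in sampled_controls},
        final_asd=frozenset(final_asd),
        final_control=frozenset(final_control),
        stage_counts=stage_counts,
    )
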