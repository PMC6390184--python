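"""Mean-of-proportions normalization.

Each user's category count is divided by that user's total tweet count over
the study window, giving a per-user proportion in [0, 1]; the group summary
is the arithmetic mean (and sample SD, n-1 denominator) of those per-user
proportions. Normalizing per user first keeps prolific accounts from
dominating the group signal.

Users with zero in-window tweets have no defined proportion and are excluded
(with a warning) rather than silently counted as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CategoryCountTable

__all__ = ["ProportionSummary", "user_proportion", "summarize_group",
           "proportion_table", "group_summaries"]


class ZeroTweetUserError(ValueError):
    """Raised when a proportion is requested for a user with no tweets."""


@dataclass(frozen=True)
class ProportionSummary:
    """Group-level summary of per-user proportions for one category."""

    group: str
    category: str
    n_users: int
    mean_of_proportions: float
    sd_of_proportions: float


def user_proportion(matched: int, total: int) -> float:
    """One user's category proportion, ``matched / total``."""
    if total <= 0:
        raise ZeroTweetUserError(
            "proportion undefined for a user with zero tweets; exclude the user"
        )
    if not 0 <= matched <= total:
        raise ValueError("matched must lie in [0, total]")
    return matched / total


def summarize_group(proportions: Sequence[float], group: str,
                    category: str) -> ProportionSummary:
    """Mean and sample SD of a group's per-user proportions."""
    x = np.asarray(proportions, dtype=float)
    if x.size == 0:
        raise ValueError("empty proportion collection")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return ProportionSummary(group=group, category=category, n_users=int(x.size),
                             mean_of_proportions=float(x.mean()),
                             sd_of_proportions=sd)


def proportion_table(table: CategoryCountTable) -> pd.DataFrame:
    """Per-user proportions for every column of a count table.

    Users with zero total tweets are dropped with a warning; the result is a
    DataFrame indexed by user_id with one proportion column per category.
    """
    totals = table.totals
    zero = totals[totals == 0]
    if len(zero):
        warnings.warn(
            f"excluding {len(zero)} user(s) with zero in-window tweets: "
            f"{list(zero.index[:5])}{'...' if len(zero) > 5 else ''}",
            stacklevel=2,
        )
    keep = totals[totals > 0]
    return table.counts.loc[keep.index].div(keep, axis=0)


def group_summaries(props: pd.DataFrame,
                    groups: Mapping[str, str]) -> list[ProportionSummary]:
    """Summarize every (group, category) cell of a per-user proportion table.

    ``groups`` maps user_id -> group name; users absent from the map are
    ignored.
    """
    out: list[ProportionSummary] = []
    glabels = props.index.to_series().map(dict(groups)).dropna()
    for gname in dict.fromkeys(glabels):
        sub = props.loc[glabels[glabels == gname].index]
        for cat in props.columns:
            out.append(summarize_group(sub[cat].to_numpy(), gname, cat))
    return out
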