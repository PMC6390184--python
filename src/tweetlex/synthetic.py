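"""Seeded synthetic corpus generator.

Emulates the statistical structure the analysis consumes, without any
platform access: two candidate cohorts with planted contamination (bots and
inaccessible accounts), heavy-tailed per-user activity (lognormal
moment-matched to target mean/SD, truncated at >= 1 tweet), per-category
keyword injection at configured per-tweet rates, local-clock posting times
drawn from per-group 6-hour multinomials, account-level UTC-offset
availability, self-identification terms for case users, and coder labels
consistent with ground truth (optionally with disagreements to exercise the
tie-break path).

Tweet text has no linguistic realism: each tweet is a short sentence of
filler words drawn from a vocabulary provably disjoint from every lexicon
form, with the matched categories' forms appended. Timestamps are placed so
every generated tweet falls strictly inside the study window in UTC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .lexicons import (builtin_asd_identification_terms,
                       builtin_emotion_lexicon, builtin_ocd_lexicon)
from .records import (AccountStatus, DEFAULT_WINDOW, Group, StudyWindow,
                      UserRecord)
from .screening import CoderLabel

__all__ = ["SyntheticConfig", "SyntheticCorpus", "generate_corpus",
           "default_study_config", "FILLER_VOCABULARY"]

#: Filler vocabulary for synthetic tweet text. Checked at generation time to
#: be disjoint from every form of the built-in lexicons and the
#: self-identification terms.
FILLER_VOCABULARY = (
    "river stone maple cedar harbor meadow lantern copper valley ember "
    "willow summit quartz garden thistle harvest timber anchor breeze saddle "
    "marble canyon pepper walnut juniper gravel tunnel mirror beacon drift "
    "saffron cobble hollow ridge barley tundra lagoon pylon orchard plume "
    "basalt heron kestrel otter lichen moss fjord delta mesa prairie"
).split()

_CONTAM_REASONS = ("bot_spam", "private", "deleted", "deactivated", "banned")
_REASON_STATUS = {"private": "private", "deleted": "deleted",
                  "deactivated": "deactivated", "banned": "banned"}
#: A handful of plausible account timezones (seconds east of UTC).
_TZ_CHOICES = (-28800, -25200, -21600, -18000, -14400, 0, 3600, 19800, 36000)


class GroupActivity(BaseModel):
    """Target mean/SD of per-user total tweets plus metadata moments."""

    mean_tweets: float = Field(gt=0)
    sd_tweets: float = Field(ge=0)
    retweet_fraction: float = Field(ge=0, le=1, default=0.0)
    mean_friends: float = 1000.0
    sd_friends: float = 3000.0
    mean_followers: float = 1500.0
    sd_followers: float = 5000.0
    mean_favorites: float = 10000.0
    sd_favorites: float = 20000.0


class SyntheticConfig(BaseModel):
    """Every planted quantity of a synthetic corpus.

    ``category_rates[group][category]`` is the per-tweet probability that a
    tweet of that group's users contains a form of that category; injection
    is independent across categories (so multi-category tweets arise at the
    product rate), plus an optional ``overlap_rate`` that forces an extra
    second category onto a matching tweet. ``user_rate_heterogeneity`` > 0
    replaces the shared rate with a per-user Beta draw of the same mean
    (variance h*p*(1-p)), emulating the large between-user spread seen in
    real cohorts.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_asd_candidates: int = Field(gt=0)
    n_control_candidates: int = Field(gt=0)
    contamination: dict[str, dict[str, int]] = Field(default_factory=dict)
    activity: dict[str, GroupActivity]
    category_rates: dict[str, dict[str, float]]
    overlap_rate: float = Field(ge=0, le=1, default=0.0)
    user_rate_heterogeneity: float = Field(ge=0, lt=1, default=0.0)
    timing_probs: dict[str, tuple[float, float, float, float]]
    offset_availability: float = Field(ge=0, le=1)
    coder_disagreement_rate: float = Field(ge=0, le=1, default=0.0)
    window: StudyWindow = DEFAULT_WINDOW
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for g, probs in self.timing_probs.items():
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"timing_probs[{g!r}] must sum to 1")
        for g, rates in self.category_rates.items():
            for c, r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"rate out of [0,1]: {g}/{c}={r}")
        sizes = {"asd": self.n_asd_candidates,
                 "control": self.n_control_candidates}
        for g, cmap in self.contamination.items():
            bad = set(cmap) - set(_CONTAM_REASONS)
            if bad:
                raise ValueError(f"unknown contamination reasons {bad}")
            if sum(cmap.values()) > sizes.get(g, 0):
                raise ValueError(
                    f"contamination for {g!r} exceeds candidate count")
        return self


@dataclass(frozen=True)
class SyntheticCorpus:
    """Generated corpus plus the ground truth that was planted."""

    users: list[UserRecord]
    tweets: pd.DataFrame  # tweet_id, user_id, text, created_at_s, utc_offset_s, is_retweet
    coder_labels: list[CoderLabel]
    truth: dict


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment match: heavy tail whenever sd > mean
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float,
                    size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    mu, sigma = _lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size)


def _all_lexicon_tokens() -> set[str]:
    toks: set[str] = set()
    for lex in (builtin_emotion_lexicon(), builtin_ocd_lexicon()):
        for cat in lex.values():
            for f in cat.forms:
                toks.update(f.split())
    for t in builtin_asd_identification_terms():
        toks.update(t.split())
    return toks


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a seeded corpus; identical config + seed => identical corpus."""
    rng = np.random.default_rng(config.seed)
    leak = set(FILLER_VOCABULARY) & _all_lexicon_tokens()
    if leak:  # defensive: the vocabulary is fixed, but guard against edits
        raise RuntimeError(f"filler vocabulary collides with lexicon forms: {leak}")

    lexicons = {**builtin_emotion_lexicon(), **builtin_ocd_lexicon()}
    cat_names = list(lexicons)
    cat_forms = {c: tuple(sorted(lexicons[c].forms)) for c in cat_names}
    asd_terms = builtin_asd_identification_terms()

    # pool of filler sentences; tweets reference the pool
    pool = np.array([" ".join(rng.choice(FILLER_VOCABULARY, size=k))
                     for k in rng.integers(3, 7, size=512)], dtype=object)

    window = config.window
    n_days = window.n_days
    start_epoch = int(pd.Timestamp(window.start_date, tz="UTC").timestamp())

    users: list[UserRecord] = []
    labels: list[CoderLabel] = []
    uid_list, text_chunks, created_chunks, offset_chunks, rt_chunks = [], [], [], [], []
    truth_users: dict[str, dict] = {}
    tweet_counter = 0

    group_specs = [("asd", config.n_asd_candidates, "a"),
                   ("control", config.n_control_candidates, "c")]
    for gname, n_users, prefix in group_specs:
        act = config.activity[gname]
        rates = np.array([config.category_rates.get(gname, {}).get(c, 0.0)
                          for c in cat_names])
        tprobs = np.asarray(config.timing_probs[gname], dtype=float)
        contam = config.contamination.get(gname, {})
        # assign contamination reasons to a random subset of the cohort
        reasons = [r for r in _CONTAM_REASONS for _ in range(contam.get(r, 0))]
        order = rng.permutation(n_users)
        reason_of = {int(order[i]): reasons[i] for i in range(len(reasons))}

        totals = np.maximum(1, np.round(_draw_lognormal(
            rng, act.mean_tweets, act.sd_tweets, n_users))).astype(np.int64)
        friends = np.round(_draw_lognormal(rng, act.mean_friends, act.sd_friends, n_users))
        followers = np.round(_draw_lognormal(rng, act.mean_followers, act.sd_followers, n_users))
        favorites = np.round(_draw_lognormal(rng, act.mean_favorites, act.sd_favorites, n_users))
        has_offset = rng.random(n_users) < config.offset_availability
        tz = rng.choice(_TZ_CHOICES, size=n_users)

        for i in range(n_users):
            uid = f"{prefix}{i:05d}"
            t = int(totals[i])
            # per-category match indicators
            user_rates = rates
            if config.user_rate_heterogeneity > 0:
                h = config.user_rate_heterogeneity
                k = 1.0 / h - 1.0
                user_rates = np.where(
                    rates > 0,
                    rng.beta(np.maximum(rates * k, 1e-12),
                             np.maximum((1 - rates) * k, 1e-12)),
                    0.0)
            m = rng.random((t, len(cat_names))) < user_rates
            if config.overlap_rate > 0:
                hit_rows = np.flatnonzero(m.any(axis=1))
                extra = hit_rows[rng.random(hit_rows.size) < config.overlap_rate]
                for row in extra:
                    m[row, rng.integers(0, len(cat_names))] = True

            texts = pool[rng.integers(0, len(pool), t)].copy()
            for row in np.flatnonzero(m.any(axis=1)):
                forms = [cat_forms[cat_names[ci]][rng.integers(0, len(cat_forms[cat_names[ci]]))]
                         for ci in np.flatnonzero(m[row])]
                texts[row] = texts[row] + " " + " ".join(forms)

            # one guaranteed self-identification signal per case user
            profile = "just a synthetic account"
            if gname == "asd":
                term = asd_terms[int(rng.integers(0, len(asd_terms)))]
                if rng.random() < 0.5 or t == 0:
                    profile = f"synthetic profile {term}"
                else:
                    row = int(rng.integers(0, t))
                    texts[row] = texts[row] + " " + term

            # local clock time from the group's multinomial; day clamped so
            # the UTC timestamp stays strictly inside the window
            bins = rng.choice(4, size=t, p=tprobs)
            sod = bins * 21600 + rng.integers(0, 21600, size=t)
            day = rng.integers(1, max(n_days - 1, 1) + 1, size=t)
            local_epoch = start_epoch + day * 86400 + sod
            created = local_epoch - int(tz[i])

            uid_list.append(np.repeat(uid, t))
            text_chunks.append(texts)
            created_chunks.append(created.astype(np.int64))
            off = np.full(t, float(tz[i])) if has_offset[i] else np.full(t, np.nan)
            offset_chunks.append(off)
            rt_chunks.append(rng.random(t) < act.retweet_fraction)
            tweet_counter += t

            reason = reason_of.get(i)
            status = AccountStatus(_REASON_STATUS[reason]) if reason in _REASON_STATUS \
                else AccountStatus.ACTIVE
            users.append(UserRecord(
                user_id=uid, profile_text=profile, group=Group(gname),
                statuses_count=t, friends_count=int(friends[i]),
                followers_count=int(followers[i]),
                favorites_count=int(favorites[i]),
                account_status=status,
                bot_or_spam=(reason == "bot_spam")))
            truth_users[uid] = {"group": gname, "total_tweets": t,
                                "contamination": reason,
                                "has_offset": bool(has_offset[i]),
                                "tz_offset_s": int(tz[i])}

            if gname == "asd":
                if rng.random() < config.coder_disagreement_rate:
                    wrong = int(rng.integers(1, 3))  # which coder errs
                    labels.append(CoderLabel(uid, "coder1",
                                             "not_asd" if wrong == 1 else "asd"))
                    labels.append(CoderLabel(uid, "coder2",
                                             "not_asd" if wrong == 2 else "asd"))
                    labels.append(CoderLabel(uid, "coder3", "asd"))
                else:
                    labels.append(CoderLabel(uid, "coder1", "asd"))
                    labels.append(CoderLabel(uid, "coder2", "asd"))

    tweets = pd.DataFrame({
        "tweet_id": np.char.add("t", np.arange(tweet_counter).astype(str)),
        "user_id": np.concatenate(uid_list),
        "text": np.concatenate(text_chunks),
        "created_at_s": np.concatenate(created_chunks),
        "utc_offset_s": np.concatenate(offset_chunks),
        "is_retweet": np.concatenate(rt_chunks),
    })

    truth = {
        "seed": config.seed,
        "category_rates": {g: dict(r) for g, r in config.category_rates.items()},
        "timing_probs": {g: list(p) for g, p in config.timing_probs.items()},
        "offset_availability": config.offset_availability,
        "contamination": {g: dict(c) for g, c in config.contamination.items()},
        "expected_survivors": {
            "asd": config.n_asd_candidates
            - sum(config.contamination.get("asd", {}).values()),
            "control": config.n_control_candidates
            - sum(config.contamination.get("control", {}).values()),
        },
        "users": truth_users,
    }
    return SyntheticCorpus(users=users, tweets=tweets, coder_labels=labels,
                           truth=truth)


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The default study conditions: 220+220 candidates contaminated down to
    152/182 survivors, activity and keyword rates matching the reported group
    means, the reported timing multinomials, and 69.2% offset availability.

    The split of the removed accounts across removal reasons is not reported
    anywhere, so an arbitrary fixed split is planted (30/14/10/8/6 for the
    case cohort, 14/9/6/5/4 for controls).
    """
    emotion_asd = {"fear": 3.105e-3, "anxiety": 1.914e-3, "paranoia": 1.902e-4}
    emotion_ctl = {"fear": 1.975e-3, "anxiety": 6.486e-4, "paranoia": 8.120e-5}
    ocd_asd = {"obsess": 5.826e-4, "fixate": 3.640e-5, "repeat": 8.711e-4,
               "routine": 1.027e-3, "freak": 7.584e-4, "clean": 1.068e-3,
               "check": 1.061e-2, "count": 1.427e-3, "hoard": 5.608e-5,
               "wash": 5.766e-4, "worry": 2.071e-3, "excess": 1.152e-4,
               "concern": 9.260e-4}
    ocd_ctl = {"obsess": 7.086e-4, "fixate": 1.226e-5, "repeat": 7.239e-4,
               "routine": 2.866e-4, "freak": 8.827e-4, "clean": 9.481e-4,
               "check": 6.944e-3, "count": 9.693e-4, "hoard": 4.938e-5,
               "wash": 5.986e-4, "worry": 1.878e-3, "excess": 4.816e-5,
               "concern": 4.548e-4}
    return SyntheticConfig(
        n_asd_candidates=220,
        n_control_candidates=220,
        contamination={
            "asd": {"bot_spam": 30, "private": 14, "deleted": 10,
                    "deactivated": 8, "banned": 6},
            "control": {"bot_spam": 14, "private": 9, "deleted": 6,
                        "deactivated": 5, "banned": 4},
        },
        activity={
            "asd": GroupActivity(mean_tweets=11189, sd_tweets=23019,
                                 retweet_fraction=2237 / 11189,
                                 mean_friends=1460, sd_friends=5422,
                                 mean_followers=1778, sd_followers=5753,
                                 mean_favorites=15556, sd_favorites=31966),
            "control": GroupActivity(mean_tweets=13146, sd_tweets=20159,
                                     retweet_fraction=4942 / 13146,
                                     mean_friends=1193, sd_friends=5559,
                                     mean_followers=1891, sd_followers=7752,
                                     mean_favorites=12515, sd_favorites=19978),
        },
        category_rates={"asd": {**emotion_asd, **ocd_asd},
                        "control": {**emotion_ctl, **ocd_ctl}},
        timing_probs={"asd": (0.131, 0.173, 0.336, 0.360),
                      "control": (0.138, 0.196, 0.294, 0.372)},
        offset_availability=0.692,
        window=DEFAULT_WINDOW,
        seed=seed,
    )
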