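"""End-to-end orchestration: screen -> filter -> count -> proportions ->
compare -> timing, with report tables written as CSV and a JSON run log.

The pipeline consumes either real input files (tweets JSONL, users CSV,
coder-labels CSV) or a synthetic-generation block — never both — and is
deterministic given (config, seed): rerunning with the same inputs produces
byte-identical report files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import io as tio
from .counting import CategoryCountTable, LexiconMatcher, count_corpus
from .lexicons import (EMOTION_CATEGORIES, OCD_CATEGORIES,
                       builtin_asd_identification_terms,
                       builtin_emotion_lexicon, builtin_ocd_lexicon)
from .proportions import group_summaries, proportion_table
from .records import DEFAULT_WINDOW, StudyWindow, UserRecord
from .screening import ScreeningResult, screen_cohorts
from .stats import WelchResult, welch_from_users
from .synthetic import SyntheticConfig, generate_corpus, default_study_config
from .timing import TimezoneAvailability, timezone_availability, timing_comparison

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_corpus"]

EMOTION_AGGREGATE = "any_emotion"
OCD_AGGREGATE = "any_ocd"


class ConfigurationError(ValueError):
    pass


class PipelineConfig(BaseModel):
    """What to run on and where to write.

    Exactly one input source: the three file paths, or ``synthetic`` (a full
    :class:`SyntheticConfig` or the string ``"default"`` for the packaged
    study conditions).
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    tweets_path: Optional[str] = None
    users_path: Optional[str] = None
    coder_labels_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig | str] = None
    n_controls: int = 220
    exclude_retweets: bool = False
    window: StudyWindow = DEFAULT_WINDOW
    outdir: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        has_files = any([self.tweets_path, self.users_path,
                         self.coder_labels_path])
        if has_files and self.synthetic is not None:
            raise ConfigurationError(
                "config names both real input files and a synthetic block")
        if not has_files and self.synthetic is None:
            raise ConfigurationError("no input source configured")
        if has_files and not all([self.tweets_path, self.users_path,
                                  self.coder_labels_path]):
            raise ConfigurationError(
                "real input needs tweets_path, users_path and coder_labels_path")
        return self


@dataclass
class PipelineResult:
    """Everything the pipeline computed, before/after serialization."""

    screening: ScreeningResult
    groups: dict[str, str]
    counts: CategoryCountTable
    emotion_rows: list[tio.GroupComparison]
    ocd_rows: list[tio.GroupComparison]
    characteristics_rows: list[tio.GroupComparison]
    timing_table: pd.DataFrame
    timing_chi2: dict
    tz_availability: TimezoneAvailability
    log: dict = field(default_factory=dict)


def _comparison_rows(props: pd.DataFrame, groups: dict[str, str],
                     categories: list[str]) -> list[tio.GroupComparison]:
    summaries = {(s.group, s.category): s
                 for s in group_summaries(props[categories], groups)}
    asd_ids = [u for u in props.index if groups.get(u) == "asd"]
    ctl_ids = [u for u in props.index if groups.get(u) == "control"]
    rows = []
    for cat in categories:
        a = summaries[("asd", cat)]
        c = summaries[("control", cat)]
        rows.append(tio.GroupComparison(
            category=cat,
            asd_mean=a.mean_of_proportions, asd_sd=a.sd_of_proportions,
            control_mean=c.mean_of_proportions, control_sd=c.sd_of_proportions,
            welch=_safe_welch(props.loc[asd_ids, cat].to_numpy(),
                              props.loc[ctl_ids, cat].to_numpy())))
    return rows


def _safe_welch(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Welch's test, degrading to a null comparison when neither group
    varies and the means coincide (typically a quantity that is zero for
    everyone, e.g. an unmatched category)."""
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        return WelchResult(t=0.0, df=float(len(x) + len(y) - 2),
                           p_two_tailed=1.0)
    return welch_from_users(x, y)


def _characteristics(users: list[UserRecord], tweets: pd.DataFrame,
                     groups: dict[str, str]) -> list[tio.GroupComparison]:
    """Per-user activity/metadata comparisons (overall, retweet and original
    tweet counts from the in-window corpus; friends/followers/favorites from
    the account metadata)."""
    per_user = tweets.groupby("user_id").agg(
        total=("tweet_id", "size"), retweets=("is_retweet", "sum"))
    per_user["original"] = per_user["total"] - per_user["retweets"]
    meta = {u.user_id: u for u in users}
    rows = []
    specs = [
        ("mean_overall_tweets", lambda uid: per_user["total"].get(uid, 0)),
        ("mean_retweets", lambda uid: per_user["retweets"].get(uid, 0)),
        ("mean_original_tweets", lambda uid: per_user["original"].get(uid, 0)),
        ("friends", lambda uid: meta[uid].friends_count),
        ("followers", lambda uid: meta[uid].followers_count),
        ("favorites", lambda uid: meta[uid].favorites_count),
    ]
    asd_ids = sorted(u for u, g in groups.items() if g == "asd")
    ctl_ids = sorted(u for u, g in groups.items() if g == "control")
    for name, getter in specs:
        x = np.array([float(getter(u)) for u in asd_ids])
        y = np.array([float(getter(u)) for u in ctl_ids])
        rows.append(tio.GroupComparison(
            category=name,
            asd_mean=float(x.mean()), asd_sd=float(x.std(ddof=1)),
            control_mean=float(y.mean()), control_sd=float(y.std(ddof=1)),
            welch=_safe_welch(x, y)))
    return rows


def analyze_corpus(users: list[UserRecord], tweets: pd.DataFrame,
                   coder_labels, *, window: StudyWindow = DEFAULT_WINDOW,
                   n_controls: int = 220, seed: int = 0,
                   exclude_retweets: bool = False) -> PipelineResult:
    """Run every analysis stage on an in-memory corpus."""
    n_in = len(tweets)
    start = pd.Timestamp(window.start_date, tz="UTC").timestamp()
    end = pd.Timestamp(window.end_date, tz="UTC").timestamp() + 86400
    in_window = (tweets["created_at_s"] >= start) & (tweets["created_at_s"] < end)
    tweets = tweets.loc[in_window]

    screening = screen_cohorts(users, tweets,
                               builtin_asd_identification_terms(),
                               coder_labels, n_controls=n_controls, seed=seed)
    if not screening.final_asd or not screening.final_control:
        raise ValueError("no users survived screening in one or both groups")
    groups = {**{u: "asd" for u in screening.final_asd},
              **{u: "control" for u in screening.final_control}}

    study_tweets = tweets[tweets["user_id"].isin(groups)]
    count_tweets = study_tweets
    if exclude_retweets:
        count_tweets = study_tweets[~study_tweets["is_retweet"].astype(bool)]

    lexicons = {**builtin_emotion_lexicon(), **builtin_ocd_lexicon()}
    counts = count_corpus(
        count_tweets, lexicons,
        aggregates={EMOTION_AGGREGATE: list(EMOTION_CATEGORIES),
                    OCD_AGGREGATE: list(OCD_CATEGORIES)},
        user_ids=sorted(groups))
    props = proportion_table(counts)

    emotion_rows = _comparison_rows(
        props, groups, list(EMOTION_CATEGORIES) + [EMOTION_AGGREGATE])
    ocd_rows = _comparison_rows(
        props, groups, list(OCD_CATEGORIES) + [OCD_AGGREGATE])
    characteristics = _characteristics(users, study_tweets, groups)

    timing_table, timing_chi2 = timing_comparison(study_tweets, groups)
    try:
        tz_avail = timezone_availability(groups, study_tweets)
    except ValueError:
        # all (or no) users carry offsets: no contrast to test
        from .stats import ChiSquareResult
        from .timing import TimezoneAvailability
        has = set(study_tweets.loc[
            pd.to_numeric(study_tweets["utc_offset_s"],
                          errors="coerce").notna(), "user_id"])
        w = {g: sum(1 for u, gg in groups.items() if gg == g and u in has)
             for g in ("asd", "control")}
        wo = {g: sum(1 for u, gg in groups.items() if gg == g and u not in has)
              for g in ("asd", "control")}
        tz_avail = TimezoneAvailability(
            with_offset=w, without_offset=wo,
            overall_fraction=sum(w.values()) / max(len(groups), 1),
            chi2=ChiSquareResult(chi2=0.0, df=1, p=1.0))

    log = {
        "tweets_in": int(n_in),
        "tweets_out_of_window": int(n_in - int(in_window.sum())),
        "tweets_analyzed": int(len(study_tweets)),
        "tweets_counted": int(len(count_tweets)),
        "exclude_retweets": bool(exclude_retweets),
        "seed": int(seed),
        "screening": dict(screening.stage_counts),
        "zero_tweet_users_excluded":
            int((counts.totals == 0).sum()),
    }
    return PipelineResult(screening=screening, groups=groups, counts=counts,
                          emotion_rows=emotion_rows, ocd_rows=ocd_rows,
                          characteristics_rows=characteristics,
                          timing_table=timing_table, timing_chi2=timing_chi2,
                          tz_availability=tz_avail, log=log)


def _write_timing_csv(result: PipelineResult, path: Path) -> None:
    chi = result.timing_chi2
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("group,interval,count,proportion,chi2,p\n")
        for row in result.timing_table.itertuples(index=False):
            c = chi[row.interval]
            fh.write(f"{row.group},{row.interval},{row.count},"
                     f"{row.proportion!r},{c.chi2!r},{c.p!r}\n")


def run_pipeline(config: PipelineConfig, seed: int) -> PipelineResult:
    """Load or generate the corpus, run :func:`analyze_corpus`, write reports.

    With a synthetic source, ``seed`` reseeds the generator; with file input
    it seeds only control sampling. Report files (written when ``outdir`` is
    set): ``user_characteristics.csv``, ``emotion_comparison.csv``,
    ``ocd_comparison.csv``, ``timing.csv``, ``timezone_availability.csv``,
    ``run_log.json``.
    """
    if config.synthetic is not None:
        syn = (default_study_config(seed) if isinstance(config.synthetic, str)
               else config.synthetic.model_copy(update={"seed": seed}))
        corpus = generate_corpus(syn)
        users, tweets, labels = corpus.users, corpus.tweets, corpus.coder_labels
        window = syn.window
    else:
        users = tio.read_users_csv(config.users_path)
        labels = tio.read_coder_labels_csv(config.coder_labels_path)
        window = config.window
        read = tio.read_tweets(config.tweets_path, window)
        tweets = tio.records_to_frame(read.records)

    result = analyze_corpus(users, tweets, labels, window=window,
                            n_controls=config.n_controls, seed=seed,
                            exclude_retweets=config.exclude_retweets)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        tio.write_comparison_csv(result.characteristics_rows,
                                 out / "user_characteristics.csv")
        tio.write_comparison_csv(result.emotion_rows,
                                 out / "emotion_comparison.csv")
        tio.write_comparison_csv(result.ocd_rows, out / "ocd_comparison.csv")
        _write_timing_csv(result, out / "timing.csv")
        tz = result.tz_availability
        with open(out / "timezone_availability.csv", "w", encoding="utf-8") as fh:
            fh.write("group,with_offset,without_offset,chi2,p\n")
            for g in tz.with_offset:
                fh.write(f"{g},{tz.with_offset[g]},{tz.without_offset[g]},"
                         f"{tz.chi2.chi2!r},{tz.chi2.p!r}\n")
        with open(out / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(result.log, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
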