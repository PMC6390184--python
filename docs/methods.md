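# Methods

## Analysis model

The pipeline compares two user cohorts — a self-identified case group and a
randomly sampled control group — on three surfaces:

1. **Lexical signal.** Each tweet is matched against closed keyword
   lexicons: three emotion categories (fear, anxiety, paranoia) and
   thirteen obsessive-compulsive behaviour categories taken from the
   Yale-Brown Obsessive-Compulsive Scale symptom checklist (obsess, fixate,
   repeat, routine, freak, clean, check, count, hoard, wash, worry, excess,
   concern). Every category is a curated, closed set of surface forms
   (tenses and pluralities of the root); there is no runtime stemming, so
   the category's reach is exactly its printed form list. Counting is
   deduplicated at the tweet level: a tweet with "anxious" and "anxiety"
   adds 1 to anxiety; a tweet with "anxious" and "fear" adds 1 to each
   category; an aggregate over a category set counts distinct tweets
   matching any member, so the aggregate mean is bounded above by the sum
   of member means and below by their maximum.

2. **Mean of proportions.** Per-user normalization divides each user's
   category count by that user's total in-window tweets, then averages the
   proportions across the group's users (sample SD, n−1). The group
   statistic therefore weights every user equally regardless of volume.
   Users with zero in-window tweets have no defined proportion and are
   excluded with a warning. Groups are compared per category with Welch's
   two-tailed t-test; the p-value uses Student's t at the real-valued
   Welch–Satterthwaite df (df is rounded only for display). No
   multiple-testing adjustment is applied across the 16 category tests —
   the comparison set is fixed and reported in full.

3. **Timing.** Local clock time is UTC time plus the account-level UTC
   offset; tweets without offset metadata are excluded. Local times fall
   into four 6-hour bins, closed-open at second resolution (05:59:59 is in
   the first bin, 06:00:00 in the second). Each interval is compared
   between groups with a tweet-level 2×2 Pearson chi-square (in-interval vs
   out-of-interval × group). User-level offset availability is compared
   with the same 2×2 statistic. The chi-square applies no continuity
   correction by default: on the reference 2×2 user counts (111/41 vs
   120/62) the uncorrected statistic reproduces the published value (1.953,
   printing as 2.0) and the corrected one does not. Note that published
   per-interval chi-square values for the timing table are *not*
   reproducible from the published tweet counts by the standard Pearson
   2×2 formula (the computed values differ severalfold); the original
   construction of that test is ambiguous, so this package reports the
   standard tweet-level statistic and treats the published timing
   chi-squares as out of reach. The timing *proportions* are reproduced.

## Cohort screening

Candidates are users whose tweets or profile text contain at least one
self-identification term (13 terms; plain words and hashtags; the
multi-word term matches as a contiguous token sequence). Tokenization is:
lowercase, split on whitespace, strip leading/trailing punctuation except a
leading `#` (so hashtag terms match literally and "fearless" never matches
"fear"). Two coders label each candidate; agreement decides, a third coder
breaks ties, and a disagreement without a tie-break label is a hard error
rather than a silent default. Controls are sampled uniformly without
replacement from unflagged users *before* account filtering, mirroring a
design in which a fixed number of controls is selected and then cleaned;
candidates adjudicated not-case are excluded from the control pool
entirely. Account filtering removes bot/spam-flagged users (flag takes
precedence) and inaccessible accounts, recording exactly one reason per
removed user; it is idempotent. On real data the bot/spam flag is an input;
a rate/duplicate-text heuristic is provided but off by default because no
principled threshold is available.

Retweets are *included* in counting and proportions by default (the
denominator is the user's total in-window tweets); `--exclude-retweets`
restricts counting to original tweets only. The exclusion deliberately does
not touch the timing analysis, which describes all posting activity.

## Synthetic corpus generator

The generator emulates the study conditions so the pipeline can be
validated end to end:

- **Cohorts.** 220 case + 220 control candidates by default, with planted
  contamination of 68 and 38 accounts respectively so screening yields
  exactly 152 and 182 survivors. The split of contamination across reasons
  (bots vs private vs deleted …) is not reported for the original cohort,
  so an arbitrary fixed split is used (30/14/10/8/6 and 14/9/6/5/4).
- **Activity.** Per-user total tweets are lognormal, moment-matched to the
  target mean/SD (case 11,189/23,019; control 13,146/20,159) and truncated
  at ≥1. SD > mean rules out Poisson-like models; the lognormal is the
  simplest heavy-tailed choice. Retweet flags are per-tweet Bernoulli with
  the group's retweet fraction; friends/followers/favorites counts are
  lognormal with the corresponding group moments.
- **Keyword injection.** Per tweet and per category, independent Bernoulli
  at the configured rate (defaults equal the published group mean
  proportions of all 16 categories); a matched tweet has the category form
  appended to a filler sentence. The filler vocabulary is checked at
  generation time to be disjoint from every lexicon form, so a
  zero-rate corpus provably produces zero counts. Independent injection
  gives per-user proportions whose spread is only binomial/lognormal
  sampling noise — much tighter than real between-user spread; an optional
  Beta heterogeneity parameter (`user_rate_heterogeneity`) widens it. That
  extrapolation is off by default, which is the main sense in which
  passing tests do not certify behaviour on real data: real users differ
  in topic propensity far more than the default corpus does, and real text
  has structure (duplicates, sarcasm, negation — "no fear" is a fear
  match) that raw keyword queries cannot see.
- **Timing.** Each tweet's local clock time is drawn from the group's
  4-bin multinomial (defaults: case 0.131/0.173/0.336/0.360, control
  0.138/0.196/0.294/0.372), uniform within the bin; the calendar day is
  uniform over the window, clamped one day inside both ends so the UTC
  timestamp always stays inside the window after offset subtraction. Each
  account gets a timezone from a small set of plausible world offsets;
  the offset is recorded on tweets with probability 0.692 per user.
- **Coder labels.** Consistent with ground truth; a configurable
  disagreement rate generates coder1/coder2 splits plus a coder3
  tie-break to exercise the adjudication path (default 0).

The generator returns the planted truth (rates, groups, contamination,
expected survivor counts) alongside the corpus, which is what the recovery
tests compare against.

## Numerical and interface conventions

- Study window: 2012-03-22 to 2017-07-20 inclusive; `n_days` is the
  end−start difference (1946 for the default window). Window membership is
  by UTC calendar date, inclusive of both endpoints.
- Welch's test requires n ≥ 2 per group and errors when both SDs are zero;
  inside the pipeline a category with no matches in either group degrades
  to a null comparison (t=0, p=1) so one empty category cannot abort a
  report. The chi-square errors on a zero margin; the pipeline likewise
  degrades the user-level availability test to a null result when every
  (or no) user carries offsets.
- Report CSVs render floats with `repr`, i.e. shortest round-trip
  precision, and rows in fixed category order, making reruns with the same
  seed byte-identical.
- Corpus-level counting memoizes tokenization over unique texts (identical
  text ⇒ identical match set), which makes the ~5M-tweet default corpus
  countable in seconds without changing any count.
- JSONL input accepts both the historical Twitter API v1.1 field names
  (including account-level `user.utc_offset`, propagated to the user's
  tweets) and the package's flat dialect; timestamps parse from the classic
  Twitter format or ISO-8601 and are normalized to UTC.

## Problem sizes used in validation

The test suite exercises the full default-scale synthetic study once
(440 candidate users, ~5M tweets) and otherwise uses reduced corpora
(tens of users, tens of tweets per user). The type-I-error calibration of
the counting → proportions → Welch chain uses 2000 seeded replicates of a
20+20-user null corpus with a 0.15 injection rate and ~25 tweets per user —
large enough for the t approximation to hold on discrete per-user
proportions, small enough to replicate cheaply.

## Known limitations

- Whole-token matching cannot see negation, sarcasm or quoted speech; the
  statistic measures mention rates, not affect.
- The closed form lists omit root surfaces in some categories (e.g.
  "routine", "check", "excess" match only derived forms) — deliberate
  fidelity to the curated lists, not an oversight to fix silently.
- The timing analysis conditions on offset availability, which is a
  user-level self-selection; the availability test quantifies, but cannot
  correct, that selection.
- The synthetic generator makes no attempt at linguistic realism and
  models within-user keyword clustering only through the optional Beta
  heterogeneity switch.
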