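import pytest

from tweetlex.records import DEFAULT_WINDOW
from tweetlex.synthetic import (GroupActivity, SyntheticConfig,
                                generate_corpus)


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A reduced corpus: 30+30 candidates, light activity, inflated keyword
    rates so category counts are non-trivial at small scale."""
    base = dict(
        n_asd_candidates=30,
        n_control_candidates=30,
        contamination={"asd": {"bot_spam": 4, "private": 2, "banned": 2},
                       "control": {"bot_spam": 3, "deleted": 2}},
        activity={"asd": GroupActivity(mean_tweets=80, sd_tweets=120,
                                       retweet_fraction=0.2),
                  "control": GroupActivity(mean_tweets=100, sd_tweets=110,
                                           retweet_fraction=0.35)},
        category_rates={"asd": {"fear": 0.05, "anxiety": 0.03, "count": 0.02},
                        "control": {"fear": 0.02, "anxiety": 0.01,
                                    "count": 0.02}},
        timing_probs={"asd": (0.131, 0.173, 0.336, 0.360),
                      "control": (0.138, 0.196, 0.294, 0.372)},
        offset_availability=0.7,
        window=DEFAULT_WINDOW,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(small_config())
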