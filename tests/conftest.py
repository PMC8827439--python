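from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from vaxpol.synthetic import GeneratorConfig, generate_corpus
from vaxpol.types import InteractionEvent, Tweet

ORIGIN = datetime(2013, 1, 1)


def mk_tweet(
    user="u1",
    p_anti=0.1,
    p_pro=0.8,
    p_neutral=None,
    urls=(),
    tweet_id=None,
    days=0.0,
    vaccine_related=True,
):
    if p_neutral is None:
        p_neutral = 1.0 - p_anti - p_pro
    return Tweet(
        tweet_id=tweet_id or f"t-{user}-{days}-{p_anti}-{p_pro}",
        user_id=user,
        timestamp=ORIGIN + timedelta(days=days),
        vaccine_related=vaccine_related,
        p_anti=p_anti,
        p_pro=p_pro,
        p_neutral=p_neutral,
        urls=tuple(urls),
    )


def mk_event(src, tgt, kind="mention", days=0.0):
    return InteractionEvent(src, tgt, kind, ORIGIN + timedelta(days=days))


@pytest.fixture(scope="session")
def small_corpus():
    """A modest synthetic corpus shared across read-only tests."""
    cfg = GeneratorConfig(n_users=400, n_windows=4, seed=5)
    users, tweets, events = generate_corpus(cfg)
    return cfg, users, tweets, events
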