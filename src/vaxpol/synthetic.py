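"""Synthetic vaccine-discourse corpus generator.

Emulates the statistical structure the downstream analysis assumes: users
with latent stances in configurable proportions, heavy-tailed per-user
activity, per-tweet sentiment probability triples concentrated around the
author's latent stance, reciprocal mention/retweet interactions with tunable
stance homophily across consecutive 3-month windows, and URL shares drawn
from stance-conditional distributions over a fixed domain vocabulary.

All randomness flows from a single root seed through named substreams
(users / tweets / interactions / urls), so the same seed yields
byte-identical corpora while the components stay independently perturbable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import yaml

from vaxpol.types import InteractionEvent, Tweet

STANCES = ("anti", "pro", "neutral")

# Substream indices off the root SeedSequence; fixed so that regenerating one
# component never perturbs another.
_STREAMS = {"users": 0, "tweets": 1, "interactions": 2, "urls": 3}

#: Default domain vocabulary: 18 domains with a stance-leaning split, mirroring
#: the observation that anti- and pro-vaccine users draw their top sources from
#: largely disjoint sets of sites.
DEFAULT_VOCAB = (
    "articles.mercola.com",
    "bbc.com",
    "cdc.gov",
    "cnn.com",
    "facebook.com",
    "healthimpactnews.com",
    "infowars.com",
    "naturalnews.com",
    "nbcnews.com",
    "nytimes.com",
    "realfarmacy.com",
    "reuters.com",
    "sciencedaily.com",
    "theguardian.com",
    "vaccineimpact.com",
    "webmd.com",
    "worldtruth.tv",
    "youtube.com",
)

_ANTI_LEANING = (
    "articles.mercola.com",
    "facebook.com",
    "healthimpactnews.com",
    "infowars.com",
    "naturalnews.com",
    "realfarmacy.com",
    "vaccineimpact.com",
    "worldtruth.tv",
    "youtube.com",
)
_PRO_LEANING = (
    "bbc.com",
    "cdc.gov",
    "cnn.com",
    "facebook.com",
    "nbcnews.com",
    "nytimes.com",
    "reuters.com",
    "sciencedaily.com",
    "theguardian.com",
    "webmd.com",
    "youtube.com",
)

# Mean of the Dirichlet sentiment law, per latent stance, over
# (p_anti, p_pro, p_neutral).
_SENTIMENT_MEANS = {
    "anti": np.array([0.75, 0.10, 0.15]),
    "pro": np.array([0.10, 0.75, 0.15]),
    "neutral": np.array([0.10, 0.15, 0.75]),
}


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _default_domain_dists() -> dict[str, dict[str, float]]:
    """Stance-conditional categorical distributions over DEFAULT_VOCAB.

    In-leaning domains carry ~90% of a stance group's mass; the remainder is
    spread uniformly, so the groups' source distributions are well separated
    but overlapping (both groups use the shared platforms).
    """
    dists: dict[str, dict[str, float]] = {}
    leaning = {
        "anti": _ANTI_LEANING,
        "pro": _PRO_LEANING,
        "neutral": _PRO_LEANING,  # neutral users skew mainstream
    }
    in_mass = {"anti": 0.9, "pro": 0.9, "neutral": 0.6}
    for stance in STANCES:
        fav = leaning[stance]
        w = {}
        for d in DEFAULT_VOCAB:
            w[d] = in_mass[stance] / len(fav) if d in fav else 0.0
        rest = 1.0 - sum(w.values())
        for d in DEFAULT_VOCAB:
            w[d] += rest / len(DEFAULT_VOCAB)
        dists[stance] = w
    return dists


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    Defaults encode the study conditions the generator emulates: a stance
    mixture of roughly 3% anti-vaccine and 45% pro-vaccine users, heavy-tailed
    per-user activity, four consecutive 91-day windows, and sentiment triples
    sharp enough that a user's tweets usually reflect their latent stance.
    """

    n_users: int = 2000
    stance_mix: tuple[float, float, float] = (0.03, 0.45, 0.52)
    activity_dist: dict = field(
        default_factory=lambda: {
            "name": "lognormal",
            "mu": 1.3,
            "sigma": 1.0,
            "max": 500,
        }
    )
    sentiment_concentration: float = 12.0
    n_windows: int = 4
    interaction_rate: float = 2.0
    homophily: float = 0.7
    url_rate: float = 0.4
    domain_dists: dict[str, dict[str, float]] | None = None
    rewire_rate: float = 0.3
    seed: int = 0
    window_days: int = 91
    origin: datetime = field(default_factory=lambda: datetime(2013, 1, 1))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_users < 1:
            raise ConfigurationError("n_users must be positive")
        mix = tuple(float(x) for x in self.stance_mix)
        if len(mix) != 3 or any(x < 0 for x in mix):
            raise ConfigurationError("stance_mix must be 3 nonnegative proportions")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigurationError(f"stance_mix sums to {sum(mix)}, not 1")
        if not (0.5 <= self.homophily <= 1.0):
            raise ConfigurationError("homophily must lie in [0.5, 1]")
        for name in ("sentiment_concentration", "interaction_rate", "url_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not (0.0 <= self.rewire_rate <= 1.0):
            raise ConfigurationError("rewire_rate must lie in [0, 1]")
        if self.n_windows < 1:
            raise ConfigurationError("n_windows must be at least 1")
        if self.domain_dists is not None:
            for stance in STANCES:
                dist = self.domain_dists.get(stance)
                if dist is None:
                    raise ConfigurationError(f"domain_dists missing stance {stance!r}")
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9 or any(v < 0 for v in dist.values()):
                    raise ConfigurationError(
                        f"domain_dists[{stance!r}] is not a distribution"
                    )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["origin"] = self.origin.isoformat()
        d["stance_mix"] = list(self.stance_mix)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "origin" in d and isinstance(d["origin"], str):
            d["origin"] = datetime.fromisoformat(d["origin"])
        if "stance_mix" in d:
            d["stance_mix"] = tuple(d["stance_mix"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- derived ------------------------------------------------------------

    @property
    def vocab(self) -> tuple[str, ...]:
        if self.domain_dists is None:
            return DEFAULT_VOCAB
        doms = set()
        for dist in self.domain_dists.values():
            doms.update(dist)
        return tuple(sorted(doms))

    def resolved_domain_dists(self) -> dict[str, dict[str, float]]:
        return self.domain_dists if self.domain_dists is not None else _default_domain_dists()

    def rng(self, stream: str) -> np.random.Generator:
        seq = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(seq)


@dataclass(frozen=True)
class LatentUser:
    """Ground-truth user record; the latent stance exists only for evaluation
    and parameter-recovery tests and is never read by the analysis modules."""

    user_id: str
    latent_stance: str
    n_tweets: int


# ---------------------------------------------------------------------------
# users


def generate_users(config: GeneratorConfig) -> list[LatentUser]:
    """Draw ``n_users`` users with multinomial latent stances and heavy-tailed
    vaccine-tweet counts."""
    config.validate()
    rng = config.rng("users")
    mix = np.asarray(config.stance_mix, dtype=float)
    stance_idx = rng.choice(3, size=config.n_users, p=mix)

    dist = config.activity_dist
    if dist.get("name", "lognormal") != "lognormal":
        raise ConfigurationError(f"unknown activity_dist {dist.get('name')!r}")
    mu, sigma = float(dist.get("mu", 1.3)), float(dist.get("sigma", 1.0))
    cap = int(dist.get("max", 500))
    counts = np.floor(rng.lognormal(mean=mu, sigma=sigma, size=config.n_users))
    counts = np.minimum(counts, cap).astype(int)

    width = len(str(config.n_users))
    return [
        LatentUser(
            user_id=f"u{i:0{width}d}",
            latent_stance=STANCES[stance_idx[i]],
            n_tweets=int(counts[i]),
        )
        for i in range(config.n_users)
    ]


# ---------------------------------------------------------------------------
# tweets


def generate_tweets(
    users: Sequence[LatentUser], config: GeneratorConfig
) -> list[Tweet]:
    """Emit per-user tweets with Dirichlet sentiment triples and URL shares.

    The sentiment triple mean is shifted toward the author's latent stance;
    ``sentiment_concentration`` is the Dirichlet precision (larger = sharper).
    URL counts are Poisson(``url_rate``); domains come from the latent
    stance's categorical distribution.  Timestamps are uniform over the full
    window span.
    """
    if not users:
        raise ConfigurationError("users must be nonempty")
    config.validate()
    rng = config.rng("tweets")
    rng_urls = config.rng("urls")
    vocab = list(config.vocab)
    dists = config.resolved_domain_dists()
    probs = {
        s: np.array([dists[s].get(d, 0.0) for d in vocab], dtype=float)
        for s in STANCES
    }
    for s in STANCES:
        probs[s] = probs[s] / probs[s].sum()

    span_days = config.n_windows * config.window_days
    tweets: list[Tweet] = []
    serial = 0
    for user in users:
        alpha = config.sentiment_concentration * _SENTIMENT_MEANS[user.latent_stance]
        alpha = np.maximum(alpha, 1e-3)
        for _ in range(user.n_tweets):
            triple = rng.dirichlet(alpha)
            offset_days = rng.uniform(0.0, span_days)
            ts = config.origin + timedelta(days=float(offset_days))
            n_urls = rng_urls.poisson(config.url_rate)
            urls: list[str] = []
            if n_urls > 0:
                idx = rng_urls.choice(len(vocab), size=n_urls, p=probs[user.latent_stance])
                urls = [f"https://{vocab[j]}/p/{serial}-{k}" for k, j in enumerate(idx)]
            tweets.append(
                Tweet(
                    tweet_id=f"t{serial:08d}",
                    user_id=user.user_id,
                    timestamp=ts,
                    vaccine_related=True,
                    p_anti=float(triple[0]),
                    p_pro=float(triple[1]),
                    p_neutral=float(triple[2]),
                    urls=tuple(urls),
                )
            )
            serial += 1
    return tweets


# ---------------------------------------------------------------------------
# interactions


def _draw_partner(
    rng: np.random.Generator,
    user_idx: int,
    group_of: np.ndarray,
    group_members: dict[int, np.ndarray],
    homophily: float,
    n_users: int,
) -> int:
    """Draw one interaction partner for ``user_idx``.

    With probability ``2 h − 1`` the partner is forced in-group; otherwise it
    is uniform over all other users.  This planted-partition mixture makes
    h = 0.5 exactly stance-blind (assortativity ~ 0) and h = 1 fully
    homophilous, regardless of group sizes.
    """
    force_in_group = rng.random() < (2.0 * homophily - 1.0)
    if force_in_group:
        members = group_members[int(group_of[user_idx])]
        if len(members) > 1:
            while True:
                j = int(members[rng.integers(len(members))])
                if j != user_idx:
                    return j
        # singleton group: fall through to uniform draw
    while True:
        j = int(rng.integers(n_users))
        if j != user_idx:
            return j


def generate_interactions(
    users: Sequence[LatentUser], config: GeneratorConfig
) -> list[InteractionEvent]:
    """Emit reciprocal mention/retweet events across consecutive windows.

    Each user holds a partner set; per window every realized pair emits two
    directed events of the same kind.  Between windows each partner is
    independently resampled with probability ``rewire_rate``, which drives
    the temporal decay of edge-set Jaccard similarity.
    """
    config.validate()
    if not users:
        raise ConfigurationError("users must be nonempty")
    rng = config.rng("interactions")
    n = len(users)
    group_of = np.array([STANCES.index(u.latent_stance) for u in users])
    group_members = {g: np.flatnonzero(group_of == g) for g in range(3)}

    # initial partner lists
    partners: list[list[int]] = []
    for i in range(n):
        k = rng.poisson(config.interaction_rate)
        partners.append(
            [
                _draw_partner(rng, i, group_of, group_members, config.homophily, n)
                for _ in range(k)
            ]
            if n > 1
            else []
        )

    events: list[InteractionEvent] = []
    window_len = timedelta(days=config.window_days)
    for w in range(config.n_windows):
        if w > 0 and config.rewire_rate > 0:
            for i in range(n):
                for slot in range(len(partners[i])):
                    if rng.random() < config.rewire_rate:
                        partners[i][slot] = _draw_partner(
                            rng, i, group_of, group_members, config.homophily, n
                        )
        pairs = sorted(
            {(min(i, j), max(i, j)) for i in range(n) for j in partners[i]}
        )
        mid = config.origin + window_len * w + window_len / 2
        for a, b in pairs:
            kind = "mention" if rng.random() < 0.5 else "retweet"
            jitter = timedelta(days=float(rng.uniform(-10.0, 10.0)))
            ts = mid + jitter
            events.append(
                InteractionEvent(users[a].user_id, users[b].user_id, kind, ts)
            )
            events.append(
                InteractionEvent(users[b].user_id, users[a].user_id, kind, ts)
            )
    return events


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[LatentUser], list[Tweet], list[InteractionEvent]]:
    """Generate users, tweets and interaction events in one call."""
    users = generate_users(config)
    tweets = generate_tweets(users, config)
    events = generate_interactions(users, config)
    return users, tweets, events
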