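"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

_SIMPLEX_TOL = 1e-6

STANCE_LABELS = ("antivaxx", "provaxx", "unassigned")


@dataclass(frozen=True)
class Tweet:
    """One vaccine-related post with classifier-style sentiment probabilities.

    ``p_anti``, ``p_pro`` and ``p_neutral`` are the probabilities that the
    tweet expresses anti-vaccine, pro-vaccine, or neutral/unrelated sentiment;
    they must form a probability triple (sum to 1).  ``urls`` holds the raw
    URL strings shared in the tweet.
    """

    tweet_id: str
    user_id: str
    timestamp: datetime
    vaccine_related: bool
    p_anti: float
    p_pro: float
    p_neutral: float
    urls: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for p in (self.p_anti, self.p_pro, self.p_neutral):
            if not (-_SIMPLEX_TOL <= p <= 1.0 + _SIMPLEX_TOL):
                raise ValueError(f"probability {p!r} outside [0, 1]")
        total = self.p_anti + self.p_pro + self.p_neutral
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"sentiment triple sums to {total!r}, not 1")


@dataclass(frozen=True)
class InteractionEvent:
    """One directed mention or retweet between two users."""

    source_id: str
    target_id: str
    kind: str  # "mention" | "retweet"
    timestamp: datetime

    def __post_init__(self) -> None:
        if self.kind not in ("mention", "retweet"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")


@dataclass(frozen=True)
class ProfileStance:
    """Per-user stance aggregate.

    ``frac_anti_tweets`` is the fraction of the user's vaccine-related tweets
    whose anti-vaccine probability met the tweet-level threshold (and likewise
    for pro).  ``label`` is "antivaxx", "provaxx" or "unassigned".
    """

    user_id: str
    n_vax_tweets: int
    mean_p_anti: float
    mean_p_pro: float
    frac_anti_tweets: float
    frac_pro_tweets: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in STANCE_LABELS:
            raise ValueError(f"unknown stance label {self.label!r}")
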