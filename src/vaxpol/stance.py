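"""Profile-level stance attribution from per-tweet sentiment probabilities.

A profile is labeled anti-vaccine (pro-vaccine) when at least half of its
vaccine-related tweets carry an anti (pro) probability of at least 50%; both
thresholds are configurable and applied inclusively.  Profiles qualifying for
both labels, or neither, stay unassigned — the labels are mutually exclusive
and the conflict can only occur at the exact threshold boundary.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from vaxpol.types import ProfileStance, Tweet

logger = logging.getLogger(__name__)


def attribute_stance(
    tweets_of_user: Sequence[Tweet],
    tweet_threshold: float = 0.5,
    profile_threshold: float = 0.5,
) -> ProfileStance:
    """Aggregate one user's vaccine-related tweets into a ProfileStance.

    Only tweets flagged ``vaccine_related`` are considered.  An empty tweet
    list yields an unassigned profile with ``n_vax_tweets == 0``.

    Raises
    ------
    ValueError
        If the tweets do not all share one user id.
    """
    user_ids = {t.user_id for t in tweets_of_user}
    if len(user_ids) > 1:
        raise ValueError(f"tweets span multiple users: {sorted(user_ids)}")
    user_id = user_ids.pop() if user_ids else ""

    vax = [t for t in tweets_of_user if t.vaccine_related]
    n = len(vax)
    if n == 0:
        return ProfileStance(user_id, 0, 0.0, 0.0, 0.0, 0.0, "unassigned")

    p_anti = np.array([t.p_anti for t in vax])
    p_pro = np.array([t.p_pro for t in vax])
    frac_anti = float(np.count_nonzero(p_anti >= tweet_threshold)) / n
    frac_pro = float(np.count_nonzero(p_pro >= tweet_threshold)) / n

    anti_fires = frac_anti >= profile_threshold
    pro_fires = frac_pro >= profile_threshold
    if anti_fires and not pro_fires:
        label = "antivaxx"
    elif pro_fires and not anti_fires:
        label = "provaxx"
    else:
        label = "unassigned"

    return ProfileStance(
        user_id=user_id,
        n_vax_tweets=n,
        mean_p_anti=float(p_anti.mean()),
        mean_p_pro=float(p_pro.mean()),
        frac_anti_tweets=frac_anti,
        frac_pro_tweets=frac_pro,
        label=label,
    )


def attribute_all(
    tweets: Iterable[Tweet],
    tweet_threshold: float = 0.5,
    profile_threshold: float = 0.5,
) -> dict[str, ProfileStance]:
    """Group a tweet stream by user and attribute a stance to every user."""
    by_user: dict[str, list[Tweet]] = defaultdict(list)
    for t in tweets:
        by_user[t.user_id].append(t)
    return {
        uid: attribute_stance(ts, tweet_threshold, profile_threshold)
        for uid, ts in sorted(by_user.items())
    }


def stance_distribution(
    profiles: Sequence[ProfileStance],
) -> dict[str, float]:
    """Proportions of antivaxx / provaxx / unassigned profiles (sum to 1)."""
    if not profiles:
        raise ValueError("profile list is empty")
    n = len(profiles)
    counts = {"antivaxx": 0, "provaxx": 0, "unassigned": 0}
    for p in profiles:
        counts[p.label] += 1
    return {k: v / n for k, v in counts.items()}


def decile_bin_users(
    all_tweet_p_anti: Sequence[float],
    user_means: Mapping[str, float],
    user_counts: Mapping[str, int] | None = None,
    min_tweets: int = 5,
    n_bins: int = 10,
) -> dict[str, int]:
    """Assign users to stance deciles.

    Bin edges are the 10%, 20%, …, 90% quantiles of the *tweet-level*
    probability distribution; each user's *mean* probability is then placed
    into bin k when it lies in [edge_{k−1}, edge_k), with the last bin
    right-closed.  Users with fewer than ``min_tweets`` vaccine-related tweets
    (per ``user_counts``) are excluded before binning.  Duplicate quantile
    edges are merged into a single bin with a warning, so the returned bin
    ids are contiguous 1..m with m ≤ ``n_bins``.
    """
    vals = np.asarray(list(all_tweet_p_anti), dtype=float)
    if vals.size == 0:
        raise ValueError("no tweet-level values to compute quantiles from")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(vals, qs)
    unique_edges = np.unique(edges)
    if len(unique_edges) < len(edges):
        msg = (
            f"{len(edges) - len(unique_edges)} duplicate decile edges; "
            f"merging affected bins ({len(unique_edges) + 1} bins remain)"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    out: dict[str, int] = {}
    for user, mean in user_means.items():
        if user_counts is not None and user_counts.get(user, 0) < min_tweets:
            continue
        # searchsorted(..., 'right') puts mean == edge_k into bin k+1,
        # giving [edge_{k-1}, edge_k) intervals, last bin right-closed.
        out[user] = int(np.searchsorted(unique_edges, mean, side="right")) + 1
    return out
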