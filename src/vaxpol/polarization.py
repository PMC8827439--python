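"""Polarization and echo-chamber statistics on the MMR graph.

Homophily is quantified by the stance assortativity (Pearson correlation of
stance values over ordered edge endpoints) and by Pearson correlations of
continuous mean sentiments between neighbors, with error bars from the
Fisher z-transform: bounds = tanh(arctanh(r) ± 1/sqrt(n−3)).

The epistemic echo chamber is profiled by binning users into stance deciles
and measuring, per decile, the Jensen-Shannon distance between the link
(domain) distribution in the users' network vicinity and the global link
distribution, with a bootstrap over the decile's users for the spread.
JS distance is the square root of the base-2 Jensen-Shannon divergence:
0 for identical distributions, 1 for disjoint supports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import jensenshannon

from vaxpol import links as link_mod
from vaxpol.types import Tweet

logger = logging.getLogger(__name__)

_STANCE_VALUE = {"antivaxx": -1.0, "provaxx": 1.0}
_AXES = ("anti", "pro")


@dataclass(frozen=True)
class CorrelationWithCI:
    """Pearson correlation with a one-standard-deviation Fisher interval."""

    r: float
    n: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.r <= self.upper):
            raise ValueError("interval does not bracket r")


@dataclass(frozen=True)
class EchoBin:
    """One cell of the echo-chamber profile.

    ``js_distance`` is the plug-in JS distance between the bin's pooled local
    link distribution and the global one.  Plug-in distances of finite pools
    are biased away from zero, and the bias depends on the pooled link count,
    so bins of different sizes are not directly comparable.  ``null_mean`` is
    the expected distance of an equal-size link pool drawn from the global
    distribution itself; ``excess`` (= js_distance − null_mean) is the
    bias-adjusted echo signal, ~0 when the vicinity shares typical sources.
    """

    axis: str  # "anti" | "pro"
    decile: int
    n_users: int
    js_distance: float
    bootstrap_sd: float
    null_mean: float = 0.0

    @property
    def excess(self) -> float:
        return self.js_distance - self.null_mean


# ---------------------------------------------------------------------------
# correlations


def fisher_interval(r: float, n: int) -> tuple[float, float]:
    """One-sd interval on a Pearson correlation via the Fisher transform."""
    if n <= 3:
        raise ValueError(f"Fisher interval undefined for n={n} (need n > 3)")
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    sd = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(z - sd)), float(np.tanh(z + sd))


def _ordered_endpoint_values(
    g: nx.Graph, value_of: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for u, v in g.edges():
        xs.extend((value_of[u], value_of[v]))
        ys.extend((value_of[v], value_of[u]))
    return np.asarray(xs), np.asarray(ys)


def stance_assortativity(
    g: nx.Graph, labels: Mapping[str, str]
) -> float:
    """Assortativity of discrete stance over the graph's edges.

    Stances map to numeric values (antivaxx → −1, provaxx → +1); the
    statistic is the Pearson correlation of these values over the two
    endpoints of every edge, each edge contributing both orientations —
    identical to Newman's numeric-attribute assortativity.
    """
    missing = [u for u in g.nodes() if u not in labels]
    if missing:
        raise ValueError(f"{len(missing)} graph nodes lack a stance label")
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    values = {u: _STANCE_VALUE[labels[u]] for u in g.nodes()}
    x, y = _ordered_endpoint_values(g, values)
    if np.std(x) == 0:
        raise ValueError("all edge endpoints share one stance; assortativity undefined")
    return float(np.corrcoef(x, y)[0, 1])


def neighbor_sentiment_correlation(
    g: nx.Graph,
    means: Mapping[str, tuple[float, float]],
    pair: tuple[str, str] = ("anti", "anti"),
) -> CorrelationWithCI:
    """Correlation between a node's mean sentiment on one axis and its
    neighbors' on another, over both orientations of every edge.

    ``means`` maps user → (mean_p_anti, mean_p_pro); ``pair`` picks the
    (focal, neighbor) axes.  The Fisher interval uses n = number of ordered
    edge observations.
    """
    for axis in pair:
        if axis not in _AXES:
            raise ValueError(f"unknown axis {axis!r}")
    a1, a2 = (_AXES.index(axis) for axis in pair)
    xs, ys = [], []
    for u, v in g.edges():
        if u not in means or v not in means:
            raise ValueError(f"edge ({u}, {v}) has an endpoint without means")
        xs.extend((means[u][a1], means[v][a1]))
        ys.extend((means[v][a2], means[u][a2]))
    n = len(xs)
    if n <= 3:
        raise ValueError(f"only {n} ordered observations; need > 3")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance on a sentiment axis")
    r = float(np.corrcoef(x, y)[0, 1])
    lower, upper = fisher_interval(r, n)
    return CorrelationWithCI(r=r, n=n, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Jensen-Shannon echo profile


def js_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon distance with base-2 logarithms.

    sqrt(½ KL(P‖M) + ½ KL(Q‖M)) with M = ½(P+Q); 0 iff P = Q, at most 1
    (attained on disjoint supports).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("P and Q must be 1-d vectors of equal length")
    for name, v in (("P", p), ("Q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} sums to {v.sum()!r}, not 1")
    d = float(jensenshannon(p, q, base=2))
    if np.isnan(d):  # scipy returns nan for numerically identical inputs
        d = 0.0
    return min(d, 1.0)


def user_domain_counts(
    tweets: Iterable[Tweet],
    vocab: Sequence[str],
    redirects: Mapping[str, str] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, int], dict[str, int]]:
    """Per-user link statistics needed by the echo profile.

    Returns (vocab-restricted domain count vector per user, total shared URL
    count per user, vaccine-related tweet count per user).
    """
    index = {d: i for i, d in enumerate(vocab)}
    counts: dict[str, np.ndarray] = {}
    n_urls: dict[str, int] = {}
    n_tweets: dict[str, int] = {}
    for t in tweets:
        if not t.vaccine_related:
            continue
        n_tweets[t.user_id] = n_tweets.get(t.user_id, 0) + 1
        if t.user_id not in counts:
            counts[t.user_id] = np.zeros(len(vocab), dtype=float)
            n_urls[t.user_id] = 0
        for raw in t.urls:
            d = link_mod.base_url(raw, redirects)
            if d is None:
                continue
            n_urls[t.user_id] += 1
            if d in index:
                counts[t.user_id][index[d]] += 1
    return counts, n_urls, n_tweets


def _qualifying_users(
    counts: Mapping[str, np.ndarray],
    n_urls: Mapping[str, int],
    n_tweets: Mapping[str, int],
    min_urls: int,
    min_tweets: int,
) -> set[str]:
    return {
        u
        for u in counts
        if n_urls.get(u, 0) >= min_urls and n_tweets.get(u, 0) >= min_tweets
    }


def local_link_distribution(
    g: nx.Graph,
    focal_users: Iterable[str],
    tweets: Sequence[Tweet],
    vocab: Sequence[str],
    min_urls: int = 5,
    min_tweets: int = 5,
    radius: int = 1,
    redirects: Mapping[str, str] | None = None,
) -> np.ndarray | None:
    """Pooled link distribution in the vicinity of a set of users.

    Pools the vocab-restricted domain counts of all users within ``radius``
    hops of any focal user (the focal users themselves excluded) who shared
    at least ``min_urls`` URLs and posted at least ``min_tweets``
    vaccine-related tweets; normalized to sum 1.  Returns None when no
    qualifying neighbor shared a vocab link.
    """
    counts, n_urls, n_tweets = user_domain_counts(tweets, vocab, redirects)
    qualifying = _qualifying_users(counts, n_urls, n_tweets, min_urls, min_tweets)
    neighborhood: set[str] = set()
    focal = set(focal_users)
    for u in focal:
        if u in g:
            reached = nx.single_source_shortest_path_length(g, u, cutoff=radius)
            neighborhood.update(reached)
    neighborhood -= focal
    pooled = np.zeros(len(vocab), dtype=float)
    for u in neighborhood & qualifying:
        pooled += counts[u]
    total = pooled.sum()
    if total == 0:
        return None
    return pooled / total


def global_link_distribution(
    tweets: Sequence[Tweet],
    vocab: Sequence[str],
    min_urls: int = 5,
    min_tweets: int = 5,
    redirects: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Link distribution pooled over all qualifying users."""
    counts, n_urls, n_tweets = user_domain_counts(tweets, vocab, redirects)
    qualifying = _qualifying_users(counts, n_urls, n_tweets, min_urls, min_tweets)
    pooled = np.zeros(len(vocab), dtype=float)
    for u in qualifying:
        pooled += counts[u]
    total = pooled.sum()
    if total == 0:
        raise ValueError("no qualifying user shared a vocab link")
    return pooled / total


def echo_profile(
    g: nx.Graph,
    tweets: Sequence[Tweet],
    bins: Mapping[str, int],
    vocab: Sequence[str],
    axis: str = "anti",
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_urls: int = 5,
    min_tweets: int = 5,
    radius: int = 1,
    redirects: Mapping[str, str] | None = None,
    n_null: int = 200,
) -> list[EchoBin]:
    """Decile-binned Jensen-Shannon echo-chamber profile with bootstrap sd.

    For each stance decile the point estimate is the JS distance between the
    pooled link distribution in the bin members' network vicinity and the
    global link distribution.  The bootstrap resamples the bin's users with
    replacement ``n_bootstrap`` times, recomputing the pooled local
    distribution and its distance to the (fixed) global distribution; the
    spread is the standard deviation of those replicates.  Each bin also
    carries ``null_mean``: the mean distance over ``n_null`` multinomial
    pools of the same total link count drawn from the global distribution,
    which calibrates away the pool-size-dependent plug-in bias.  Empty bins
    and bins with no qualifying neighbor links are omitted with a warning.
    """
    counts, n_urls, n_tweets = user_domain_counts(tweets, vocab, redirects)
    qualifying = _qualifying_users(counts, n_urls, n_tweets, min_urls, min_tweets)
    pooled_all = np.zeros(len(vocab), dtype=float)
    for u in qualifying:
        pooled_all += counts[u]
    if pooled_all.sum() == 0:
        raise ValueError("no qualifying user shared a vocab link")
    global_dist = pooled_all / pooled_all.sum()

    # per-user qualifying-neighbor row indices into a count matrix
    qual_sorted = sorted(qualifying)
    row_of = {u: i for i, u in enumerate(qual_sorted)}
    matrix = np.vstack([counts[u] for u in qual_sorted]) if qual_sorted else np.zeros((0, len(vocab)))

    def neighbor_rows(u: str) -> np.ndarray:
        if u not in g:
            return np.empty(0, dtype=int)
        reached = nx.single_source_shortest_path_length(g, u, cutoff=radius)
        return np.array(
            sorted(row_of[v] for v in reached if v != u and v in row_of),
            dtype=int,
        )

    by_bin: dict[int, list[str]] = {}
    for u, b in bins.items():
        by_bin.setdefault(b, []).append(u)

    rng = np.random.default_rng(seed)
    profile: list[EchoBin] = []
    for b in sorted(by_bin):
        members = sorted(by_bin[b])
        nb = {u: neighbor_rows(u) for u in members}

        def pooled_distance(users: Sequence[str]) -> float | None:
            if not users:
                return None
            rows = np.unique(np.concatenate([nb[u] for u in users]))
            if rows.size == 0:
                return None
            local = matrix[rows].sum(axis=0)
            total = local.sum()
            if total == 0:
                return None
            return js_distance(local / total, global_dist)

        point = pooled_distance(members)
        if point is None:
            warnings.warn(
                f"bin {b} ({axis} axis): no qualifying neighbor links; omitted",
                stacklevel=2,
            )
            continue
        reps = []
        m = len(members)
        for _ in range(n_bootstrap):
            sample = [members[i] for i in rng.integers(m, size=m)]
            d = pooled_distance(sample)
            if d is not None:
                reps.append(d)
        sd = float(np.std(reps)) if reps else 0.0

        rows = np.unique(np.concatenate([nb[u] for u in members]))
        n_links = int(matrix[rows].sum())
        null_draws = rng.multinomial(n_links, global_dist, size=n_null)
        null_mean = float(
            np.mean(
                [js_distance(d / n_links, global_dist) for d in null_draws]
            )
        )
        profile.append(
            EchoBin(
                axis=axis,
                decile=b,
                n_users=m,
                js_distance=float(point),
                bootstrap_sd=sd,
                null_mean=null_mean,
            )
        )
    return profile
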