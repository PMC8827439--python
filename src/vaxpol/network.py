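"""Mutual Mention/Retweet (MMR) graph construction and structural summaries.

Two users are linked in a window when each has directed an interaction of the
same kind (mention or retweet) at the other inside that window; a flag allows
the looser mixed-kind reading.  Windows are fixed-length, half-open,
consecutive intervals (default 91 days).  The aggregated graph weights each
edge by the number of windows in which the pair interacted reciprocally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import optimize, stats

from vaxpol.types import InteractionEvent, ProfileStance

logger = logging.getLogger(__name__)

EdgeSet = frozenset  # of 2-tuples (u, v) with u < v


@dataclass(frozen=True)
class WindowSpec:
    """Consecutive, non-overlapping, half-open time windows."""

    origin: datetime = datetime(2013, 1, 1)
    days: int = 91

    @property
    def length(self) -> timedelta:
        return timedelta(days=self.days)


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull parameters for a degree distribution:
    p(k) = (beta/alpha) (k/alpha)^(beta-1) exp(−(k/alpha)^beta)."""

    alpha: float  # scale
    beta: float  # shape
    truncation: int
    loglik: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite positive, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite positive, got {self.beta}")


def window_index(timestamp: datetime, spec: WindowSpec) -> int:
    """Index of the half-open window [origin + k·L, origin + (k+1)·L)
    containing ``timestamp``; timestamps before the origin are an error."""
    delta = timestamp - spec.origin
    if delta < timedelta(0):
        raise ValueError(f"timestamp {timestamp} precedes window origin {spec.origin}")
    return int(delta // spec.length)


def drop_self_events(events: Iterable[InteractionEvent]) -> list[InteractionEvent]:
    """Remove self-interactions, logging how many were dropped."""
    kept, dropped = [], 0
    for e in events:
        if e.source_id == e.target_id:
            dropped += 1
        else:
            kept.append(e)
    if dropped:
        logger.info("dropped %d self-interaction events", dropped)
    return kept


def build_window_edges(
    events: Sequence[InteractionEvent],
    mixed_type_reciprocity: bool = False,
) -> frozenset[tuple[str, str]]:
    """Reciprocal pairs among events of a single window.

    Pair {A, B} is included iff A→B and B→A events of the same kind both
    occur (or of any kind, when ``mixed_type_reciprocity``).
    """
    seen: set[tuple[str, str, str]] = set()
    edges: set[tuple[str, str]] = set()
    for e in events:
        if e.source_id == e.target_id:
            continue
        kind = "any" if mixed_type_reciprocity else e.kind
        seen.add((e.source_id, e.target_id, kind))
        if (e.target_id, e.source_id, kind) in seen:
            a, b = sorted((e.source_id, e.target_id))
            edges.add((a, b))
    return frozenset(edges)


def window_edge_sets(
    events: Sequence[InteractionEvent],
    spec: WindowSpec,
    n_windows: int | None = None,
    mixed_type_reciprocity: bool = False,
) -> list[frozenset[tuple[str, str]]]:
    """Partition events into windows and build each window's reciprocal edge set."""
    events = drop_self_events(events)
    by_window: dict[int, list[InteractionEvent]] = {}
    max_w = -1
    for e in events:
        w = window_index(e.timestamp, spec)
        by_window.setdefault(w, []).append(e)
        max_w = max(max_w, w)
    if n_windows is None:
        n_windows = max_w + 1
    if n_windows < 1:
        raise ValueError("no windows contain events")
    return [
        build_window_edges(by_window.get(w, []), mixed_type_reciprocity)
        for w in range(n_windows)
    ]


def aggregate_mmr(
    window_edge_sets: Sequence[frozenset[tuple[str, str]]],
    spec: WindowSpec | None = None,
) -> nx.Graph:
    """Union the per-window edge sets into a weighted undirected graph.

    Edge weight = number of windows in which the pair interacted reciprocally.
    """
    if not window_edge_sets:
        raise ValueError("need at least one window edge set")
    g = nx.Graph()
    if spec is not None:
        g.graph["window_spec"] = spec
    g.graph["n_windows"] = len(window_edge_sets)
    for edges in window_edge_sets:
        for u, v in edges:
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


def threshold_graph(
    g: nx.Graph,
    min_weight: int = 1,
    min_vax_tweets: int = 0,
    profiles: Mapping[str, ProfileStance] | None = None,
    require_stance: bool = False,
) -> nx.Graph:
    """Restrict an MMR graph to repeatedly-interacting, sufficiently active
    (and optionally stance-labeled) users; isolated nodes are dropped.

    Nodes missing from ``profiles`` are dropped whenever a profile-based
    criterion is active.
    """
    def node_ok(u: str) -> bool:
        if min_vax_tweets > 0 or require_stance:
            if profiles is None or u not in profiles:
                return False
            p = profiles[u]
            if p.n_vax_tweets < min_vax_tweets:
                return False
            if require_stance and p.label == "unassigned":
                return False
        return True

    out = nx.Graph()
    out.graph.update(g.graph)
    for u, v, data in g.edges(data=True):
        if data.get("weight", 1) >= min_weight and node_ok(u) and node_ok(v):
            out.add_edge(u, v, **data)
    return out


def giant_component(g: nx.Graph) -> tuple[nx.Graph, float]:
    """Largest connected component and its node fraction.

    Size ties break toward the component containing the smallest node id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    giant = comps[0]
    return g.subgraph(giant).copy(), len(giant) / g.number_of_nodes()


# ---------------------------------------------------------------------------
# degree distribution


def _weibull_loglik(degrees: np.ndarray, alpha: float, beta: float) -> float:
    k = degrees
    return float(
        np.sum(
            np.log(beta / alpha)
            + (beta - 1) * np.log(k / alpha)
            - (k / alpha) ** beta
        )
    )


def fit_weibull_degrees(
    degrees: Iterable[int], truncation: int = 500
) -> WeibullFit:
    """Fit a two-parameter Weibull density to node degrees by maximum
    likelihood.

    Zero degrees are excluded and degrees above ``truncation`` discarded
    (very-high-degree nodes are typically automated accounts).  The density
    is the continuous Weibull, p(k) = (β/α)(k/α)^(β−1) exp(−(k/α)^β),
    evaluated on degrees in [1, truncation].
    """
    k = np.asarray([d for d in degrees if 0 < d <= truncation], dtype=float)
    if k.size < 2 or np.unique(k).size < 2:
        raise ValueError("need at least 2 distinct positive degrees to fit")
    beta, _, alpha = stats.weibull_min.fit(k, floc=0)
    # polish on our own likelihood to guard against scipy's default stopping
    res = optimize.minimize(
        lambda p: -_weibull_loglik(k, np.exp(p[0]), np.exp(p[1])),
        x0=[np.log(alpha), np.log(beta)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10},
    )
    alpha, beta = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return WeibullFit(
        alpha=alpha,
        beta=beta,
        truncation=truncation,
        loglik=_weibull_loglik(k, alpha, beta),
    )


# ---------------------------------------------------------------------------
# temporal similarity


def jaccard_edges(s_i: frozenset, s_j: frozenset) -> float:
    """Jaccard similarity |S_i ∩ S_j| / |S_i ∪ S_j|; 0 when both sets are
    empty (documented convention)."""
    union = len(s_i | s_j)
    if union == 0:
        return 0.0
    return len(s_i & s_j) / union


def jaccard_matrix(
    window_edge_sets: Sequence[frozenset],
) -> np.ndarray:
    """Symmetric matrix of pairwise Jaccard similarities between the edge
    sets of consecutive windows."""
    n = len(window_edge_sets)
    if n < 2:
        raise ValueError("need at least 2 windows")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m[i, j] = m[j, i] = jaccard_edges(
                window_edge_sets[i], window_edge_sets[j]
            )
    return m


# ---------------------------------------------------------------------------
# io


def write_graph(g: nx.Graph, path: str | Path) -> None:
    """Weighted edge list as TSV (u, v, weight), sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1)}\n")


def read_graph(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["u", "v", "weight"]:
            raise ValueError(f"unexpected graph header: {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v, w = line.split("\t")
            g.add_edge(u, v, weight=int(w))
    return g
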