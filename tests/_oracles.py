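"""Independent brute-force oracles, deliberately written from the definitions
rather than sharing any code path with the package."""

from __future__ import annotations

import math
from collections import defaultdict


def js_distance_oracle(p, q) -> float:
    """Elementwise two-KL-term Jensen-Shannon distance, base-2 logs."""
    assert len(p) == len(q)
    m = [(pi + qi) / 2.0 for pi, qi in zip(p, q)]

    def kl(a, b):
        total = 0.0
        for ai, bi in zip(a, b):
            if ai > 0:
                total += ai * math.log2(ai / bi)
        return total

    jsd = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return math.sqrt(max(jsd, 0.0))


def stance_label_oracle(
    triples, tweet_threshold=0.5, profile_threshold=0.5
) -> str:
    """Literal reading of the profile rule: a profile is anti (pro) when at
    least ``profile_threshold`` of its tweets have p_anti (p_pro) of at least
    ``tweet_threshold``; both or neither qualifying -> unassigned."""
    n = len(triples)
    if n == 0:
        return "unassigned"
    n_anti = sum(1 for (pa, pp, pn) in triples if pa >= tweet_threshold)
    n_pro = sum(1 for (pa, pp, pn) in triples if pp >= tweet_threshold)
    anti_ok = n_anti / n >= profile_threshold
    pro_ok = n_pro / n >= profile_threshold
    if anti_ok and pro_ok:
        return "unassigned"
    if anti_ok:
        return "antivaxx"
    if pro_ok:
        return "provaxx"
    return "unassigned"


def reciprocal_pairs_oracle(events, window_of, mixed=False):
    """Brute-force scan for reciprocal same-window pairs.

    ``events`` are (source, target, kind, timestamp) tuples; ``window_of``
    maps a timestamp to a window id.  Returns {window: set of (u, v) pairs
    with u < v} by checking, for every ordered pair of events, whether they
    witness reciprocity.
    """
    by_window = defaultdict(list)
    for src, tgt, kind, ts in events:
        if src == tgt:
            continue
        by_window[window_of(ts)].append((src, tgt, kind))
    out = {}
    for w, evs in by_window.items():
        pairs = set()
        for (s1, t1, k1) in evs:
            for (s2, t2, k2) in evs:
                if s1 == t2 and t1 == s2 and (mixed or k1 == k2):
                    pairs.add((min(s1, t1), max(s1, t1)))
        out[w] = pairs
    return out
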