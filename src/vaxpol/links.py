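"""URL normalization, top-domain ranking and source-category frequencies.

Raw shared URLs are resolved through an offline redirect map (a stand-in for
live crawling), then reduced to their base domain: scheme, credentials, port,
path, query and fragment are stripped, the host lowercased and a leading
"www." removed.  Subdomains are otherwise preserved, because several
well-known sources are identified by a subdomain (e.g. articles.mercola.com);
category lookups fall back to the parent domain when the exact host is
missing from the map.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import urlsplit

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CATEGORIES = (
    "commercial",
    "conspiracy",
    "news",
    "pseudoscience",
    "science",
    "social_media",
    "youtube",
)

_MAX_REDIRECTS = 10


def load_domain_categories(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load a domain→categories map; defaults to the packaged assignment of
    the most-shared domains in the vaccine discourse."""
    if path is None:
        text = (
            resources.files("vaxpol")
            .joinpath("data/domain_categories.yaml")
            .read_text()
        )
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    out: dict[str, frozenset[str]] = {}
    for domain, cats in raw.items():
        cats = frozenset(cats)
        unknown = cats - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)} for {domain!r}")
        out[domain.lower()] = cats
    return out


def load_redirects(path: str | Path) -> dict[str, str]:
    """Offline redirect map (raw URL → final URL) from JSON or YAML."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            return dict(json.load(fh))
        return dict(yaml.safe_load(fh) or {})


def _resolve(raw: str, redirects: Mapping[str, str] | None) -> str:
    if not redirects:
        return raw
    seen = {raw}
    url = raw
    for _ in range(_MAX_REDIRECTS):
        nxt = redirects.get(url)
        if nxt is None or nxt in seen:
            return url
        seen.add(nxt)
        url = nxt
    return url


def base_url(raw: str, redirects: Mapping[str, str] | None = None) -> str | None:
    """Reduce a raw URL to its base domain, or None if unparseable.

    Resolves through the redirect map first (misses fall through to the raw
    URL), then strips scheme, credentials, "www." prefix, port, path, query
    and fragment.
    """
    url = _resolve(raw.strip(), redirects)
    if "://" not in url:
        url = "http://" + url
    try:
        host = urlsplit(url).hostname
    except ValueError:
        return None
    if not host:
        return None
    host = host.lower().rstrip(".")
    if host.startswith("www."):
        host = host[4:]
    # a registrable domain has at least one dot and no whitespace
    if "." not in host or any(c.isspace() for c in host):
        return None
    return host


def base_urls(
    raws: Iterable[str], redirects: Mapping[str, str] | None = None
) -> tuple[list[str], int]:
    """Normalize many URLs; returns (domains, n_skipped) and logs the skips."""
    domains, skipped = [], 0
    for raw in raws:
        d = base_url(raw, redirects)
        if d is None:
            skipped += 1
        else:
            domains.append(d)
    if skipped:
        logger.info("skipped %d unparseable URLs", skipped)
    return domains, skipped


def categories_for(
    domain: str, cats: Mapping[str, frozenset[str]]
) -> frozenset[str]:
    """Categories for a domain: exact host first, then parent domains."""
    host = domain
    while host:
        if host in cats:
            return cats[host]
        if "." not in host:
            break
        host = host.split(".", 1)[1]
    return frozenset()


def top_domains(
    links_by_group: Mapping[str, Sequence[str]], k: int = 10
) -> tuple[dict[str, list[tuple[str, int]]], list[str], dict[str, float]]:
    """Per-group top-k domains, their deduplicated union, and coverage.

    Coverage is the fraction of a group's links that fall in its own top-k.
    Count ties break lexicographically.  Empty groups are an error.
    """
    rankings: dict[str, list[tuple[str, int]]] = {}
    coverage: dict[str, float] = {}
    union: set[str] = set()
    for group, links in links_by_group.items():
        if not links:
            raise ValueError(f"group {group!r} has no links")
        counts = Counter(links)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        rankings[group] = ranked
        union.update(d for d, _ in ranked)
        coverage[group] = sum(c for _, c in ranked) / len(links)
    return rankings, sorted(union), coverage


def category_frequencies(
    links_by_group: Mapping[str, Sequence[str]],
    cats: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """Fraction of each group's links that carry each category.

    A multi-category domain counts toward each of its categories, so rows
    need not sum to 1.  Domains absent from the category map are tallied in
    an "uncategorized" column and logged.
    """
    rows = {}
    for group, links in links_by_group.items():
        n = len(links)
        if n == 0:
            warnings.warn(f"group {group!r} has no links; fractions set to 0",
                          stacklevel=2)
            rows[group] = {c: 0.0 for c in (*CATEGORIES, "uncategorized")}
            continue
        counts = Counter()
        uncategorized = 0
        for d in links:
            cs = categories_for(d, cats)
            if not cs:
                uncategorized += 1
            for c in cs:
                counts[c] += 1
        if uncategorized:
            logger.info(
                "group %s: %d of %d links uncategorized", group, uncategorized, n
            )
        row = {c: counts.get(c, 0) / n for c in CATEGORIES}
        row["uncategorized"] = uncategorized / n
        rows[group] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
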