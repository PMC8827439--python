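"""Readers and writers for the plain-text interchange formats.

Tweets travel as JSON-lines (one object per tweet), interaction events as
TSV, and profile-stance tables as TSV.  All timestamps are ISO-8601.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Iterable

from vaxpol.types import InteractionEvent, ProfileStance, Tweet

EVENT_COLUMNS = ("source_id", "target_id", "kind", "timestamp")
PROFILE_COLUMNS = (
    "user_id",
    "n_vax_tweets",
    "mean_p_anti",
    "mean_p_pro",
    "frac_anti",
    "frac_pro",
    "label",
)


def write_tweets(tweets: Iterable[Tweet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": t.tweet_id,
                        "user_id": t.user_id,
                        "timestamp": t.timestamp.isoformat(),
                        "vaccine_related": t.vaccine_related,
                        "p_anti": t.p_anti,
                        "p_pro": t.p_pro,
                        "p_neutral": t.p_neutral,
                        "urls": list(t.urls),
                    },
                    separators=(",", ":"),
                )
                + "\n"
            )


def read_tweets(path: str | Path) -> list[Tweet]:
    tweets = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            tweets.append(
                Tweet(
                    tweet_id=obj["tweet_id"],
                    user_id=obj["user_id"],
                    timestamp=datetime.fromisoformat(obj["timestamp"]),
                    vaccine_related=bool(obj["vaccine_related"]),
                    p_anti=float(obj["p_anti"]),
                    p_pro=float(obj["p_pro"]),
                    p_neutral=float(obj["p_neutral"]),
                    urls=tuple(obj.get("urls", ())),
                )
            )
    return tweets


def write_events(events: Iterable[InteractionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(
                f"{e.source_id}\t{e.target_id}\t{e.kind}\t{e.timestamp.isoformat()}\n"
            )


def read_events(path: str | Path) -> list[InteractionEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EVENT_COLUMNS:
            raise ValueError(f"unexpected event table header: {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            src, tgt, kind, ts = line.split("\t")
            events.append(
                InteractionEvent(
                    source_id=src,
                    target_id=tgt,
                    kind=kind,
                    timestamp=datetime.fromisoformat(ts),
                )
            )
    return events


def write_profiles(profiles: Iterable[ProfileStance], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            fh.write(
                f"{p.user_id}\t{p.n_vax_tweets}\t{p.mean_p_anti:.10g}\t"
                f"{p.mean_p_pro:.10g}\t{p.frac_anti_tweets:.10g}\t"
                f"{p.frac_pro_tweets:.10g}\t{p.label}\n"
            )


def read_profiles(path: str | Path) -> list[ProfileStance]:
    profiles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PROFILE_COLUMNS:
            raise ValueError(f"unexpected profile table header: {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            uid, n, ma, mp, fa, fp, label = line.split("\t")
            profiles.append(
                ProfileStance(
                    user_id=uid,
                    n_vax_tweets=int(n),
                    mean_p_anti=float(ma),
                    mean_p_pro=float(mp),
                    frac_anti_tweets=float(fa),
                    frac_pro_tweets=float(fp),
                    label=label,
                )
            )
    return profiles
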