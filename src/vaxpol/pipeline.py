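"""End-to-end orchestration: simulate → stance → network → links → polarization.

A single RunConfig drives every stage; one root seed governs all randomness,
so a run is reproducible down to byte-identical report tables.  Reports are
plain TSV/CSV; a JSON manifest records the config, per-stage record counts
and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

import vaxpol
from vaxpol import io, links as link_mod, network, polarization, stance as stance_mod
from vaxpol.synthetic import GeneratorConfig, generate_corpus
from vaxpol.types import ProfileStance, Tweet

logger = logging.getLogger(__name__)

SWEEPABLE = ("min_weight", "tweet_threshold", "profile_threshold")


@dataclass
class RunConfig:
    """Every knob of a full pipeline run, reachable from one YAML file."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    tweet_threshold: float = 0.5
    profile_threshold: float = 0.5
    min_weight: int = 2
    min_vax_tweets: int = 5
    require_stance: bool = True
    mixed_type_reciprocity: bool = False
    top_k: int = 10
    min_urls: int = 5
    n_bootstrap: int = 1000
    radius: int = 1
    weibull_truncation: int = 500

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def smoke_config(seed: int = 7) -> RunConfig:
    """Small configuration used for smoke tests and determinism checks."""
    return RunConfig(
        generator=GeneratorConfig(n_users=500, n_windows=4, seed=seed),
        n_bootstrap=200,
    )


# ---------------------------------------------------------------------------
# in-memory analysis


def analyze_corpus(
    tweets: Sequence[Tweet],
    events,
    cfg: RunConfig,
) -> dict:
    """Run every analysis stage on an in-memory corpus; returns a dict of
    tables and fitted objects (no file IO)."""
    res: dict = {}

    # stance ---------------------------------------------------------------
    profiles = stance_mod.attribute_all(
        tweets, cfg.tweet_threshold, cfg.profile_threshold
    )
    res["profiles"] = profiles
    res["stance_distribution"] = stance_mod.stance_distribution(
        list(profiles.values())
    )
    vax_tweets = [t for t in tweets if t.vaccine_related]
    n_vax = len(vax_tweets)
    res["tweet_sentiment"] = {
        "anti": sum(t.p_anti >= cfg.tweet_threshold for t in vax_tweets) / n_vax,
        "pro": sum(t.p_pro >= cfg.tweet_threshold for t in vax_tweets) / n_vax,
    }

    # network --------------------------------------------------------------
    spec = network.WindowSpec(
        origin=cfg.generator.origin, days=cfg.generator.window_days
    )
    edge_sets = network.window_edge_sets(
        events, spec, n_windows=cfg.generator.n_windows,
        mixed_type_reciprocity=cfg.mixed_type_reciprocity,
    )
    res["window_edge_sets"] = edge_sets
    g_full = network.aggregate_mmr(edge_sets, spec)
    res["graph_full"] = g_full
    if len(edge_sets) >= 2:
        res["jaccard"] = network.jaccard_matrix(edge_sets)
    degrees = [d for _, d in g_full.degree()]
    try:
        res["weibull"] = network.fit_weibull_degrees(
            degrees, truncation=cfg.weibull_truncation
        )
    except ValueError as exc:
        logger.warning("Weibull fit skipped: %s", exc)
        res["weibull"] = None

    g_strict = network.threshold_graph(
        g_full,
        min_weight=cfg.min_weight,
        min_vax_tweets=cfg.min_vax_tweets,
        profiles=profiles,
        require_stance=cfg.require_stance,
    )
    res["graph_strict"] = g_strict
    if g_strict.number_of_nodes() > 0:
        giant, frac = network.giant_component(g_strict)
        anti_in_giant = sum(
            profiles[u].label == "antivaxx" for u in giant.nodes()
        )
        res["giant"] = {
            "n_nodes": g_strict.number_of_nodes(),
            "n_edges": g_strict.number_of_edges(),
            "giant_fraction": frac,
            "giant_nodes": giant.number_of_nodes(),
            "antivaxx_fraction_in_giant": anti_in_giant
            / max(giant.number_of_nodes(), 1),
        }
    else:
        res["giant"] = None

    # links ----------------------------------------------------------------
    label_of = {u: p.label for u, p in profiles.items()}
    group_name = {"antivaxx": "antivaxx", "provaxx": "provaxx",
                  "unassigned": "neutral"}
    links_by_group: dict[str, list[str]] = {
        "antivaxx": [], "provaxx": [], "neutral": []}
    n_skipped = 0
    for t in vax_tweets:
        grp = group_name[label_of[t.user_id]]
        domains, skipped = link_mod.base_urls(t.urls)
        n_skipped += skipped
        links_by_group[grp].extend(domains)
    res["n_unparseable_urls"] = n_skipped
    stance_groups = {
        k: v for k, v in links_by_group.items()
        if k in ("antivaxx", "provaxx") and v
    }
    if len(stance_groups) == 2:
        rankings, union, coverage = link_mod.top_domains(stance_groups, cfg.top_k)
        res["top_domains"] = rankings
        res["top_domain_union"] = union
        res["top_domain_coverage"] = coverage
    else:
        res["top_domains"] = None
        res["top_domain_union"] = sorted(
            {d for ds in links_by_group.values() for d in ds}
        )
        res["top_domain_coverage"] = None
    cats = link_mod.load_domain_categories()
    res["category_frequencies"] = link_mod.category_frequencies(
        links_by_group, cats
    )

    # polarization ---------------------------------------------------------
    labeled = {
        u: p.label for u, p in profiles.items() if p.label != "unassigned"
    }
    try:
        res["assortativity"] = polarization.stance_assortativity(
            g_strict.subgraph(
                [u for u in g_strict if u in labeled]
            ),
            labeled,
        )
    except ValueError as exc:
        logger.warning("assortativity undefined: %s", exc)
        res["assortativity"] = None

    # continuous-stance neighbor correlations vs min_weight (Fig-5 analogue)
    means = {
        u: (p.mean_p_anti, p.mean_p_pro)
        for u, p in profiles.items()
        if p.n_vax_tweets >= cfg.min_vax_tweets
    }
    corr_rows = []
    for mw in range(1, cfg.generator.n_windows + 1):
        g_mw = network.threshold_graph(
            g_full, min_weight=mw, min_vax_tweets=cfg.min_vax_tweets,
            profiles=profiles, require_stance=False,
        )
        g_mw = g_mw.subgraph([u for u in g_mw if u in means])
        for pair in (("anti", "anti"), ("pro", "pro"), ("pro", "anti")):
            try:
                c = polarization.neighbor_sentiment_correlation(g_mw, means, pair)
            except ValueError:
                continue
            corr_rows.append(
                {
                    "min_weight": mw,
                    "axes": f"{pair[0]}-{pair[1]}",
                    "r": c.r,
                    "lower": c.lower,
                    "upper": c.upper,
                    "n": c.n,
                    "n_nodes": g_mw.number_of_nodes(),
                    "n_edges": g_mw.number_of_edges(),
                }
            )
    res["correlations"] = pd.DataFrame(corr_rows)

    # echo profile ---------------------------------------------------------
    vocab = res["top_domain_union"]
    echo_rows: list[polarization.EchoBin] = []
    if vocab:
        for axis in ("anti", "pro"):
            tweet_vals = [
                (t.p_anti if axis == "anti" else t.p_pro) for t in vax_tweets
            ]
            user_means = {
                u: (p.mean_p_anti if axis == "anti" else p.mean_p_pro)
                for u, p in profiles.items()
            }
            user_counts = {u: p.n_vax_tweets for u, p in profiles.items()}
            bins = stance_mod.decile_bin_users(
                tweet_vals, user_means, user_counts,
                min_tweets=cfg.min_vax_tweets,
            )
            echo_rows.extend(
                polarization.echo_profile(
                    g_full,
                    tweets,
                    bins,
                    vocab,
                    axis=axis,
                    n_bootstrap=cfg.n_bootstrap,
                    seed=cfg.generator.seed,
                    min_urls=cfg.min_urls,
                    min_tweets=cfg.min_vax_tweets,
                    radius=cfg.radius,
                )
            )
    res["echo_profile"] = echo_rows
    return res


# ---------------------------------------------------------------------------
# file-writing run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_reports(res: dict, outdir: Path) -> None:
    io.write_profiles(res["profiles"].values(), outdir / "profiles.tsv")

    with open(outdir / "stance_distribution.tsv", "w") as fh:
        fh.write("label\tfraction\n")
        for label in ("antivaxx", "provaxx", "unassigned"):
            fh.write(f"{label}\t{res['stance_distribution'][label]:.10g}\n")

    with open(outdir / "tweet_sentiment.tsv", "w") as fh:
        fh.write("axis\tfraction_of_tweets\n")
        for axis, v in res["tweet_sentiment"].items():
            fh.write(f"{axis}\t{v:.10g}\n")

    network.write_graph(res["graph_full"], outdir / "graph_full.tsv")
    network.write_graph(res["graph_strict"], outdir / "graph.tsv")

    if res.get("jaccard") is not None:
        np.savetxt(outdir / "jaccard.csv", res["jaccard"], delimiter=",",
                   fmt="%.10g")

    with open(outdir / "network_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        if res["giant"]:
            for k, v in res["giant"].items():
                fh.write(f"{k}\t{v:.10g}\n" if isinstance(v, float) else f"{k}\t{v}\n")
        if res["weibull"]:
            w = res["weibull"]
            fh.write(f"weibull_alpha\t{w.alpha:.10g}\n")
            fh.write(f"weibull_beta\t{w.beta:.10g}\n")
            fh.write(f"weibull_loglik\t{w.loglik:.10g}\n")

    with open(outdir / "top_domains.tsv", "w") as fh:
        fh.write("group\trank\tdomain\tcount\n")
        if res["top_domains"]:
            for group in sorted(res["top_domains"]):
                for rank, (d, c) in enumerate(res["top_domains"][group], 1):
                    fh.write(f"{group}\t{rank}\t{d}\t{c}\n")

    res["category_frequencies"].to_csv(
        outdir / "category_frequencies.tsv", sep="\t", float_format="%.10g"
    )

    res["correlations"].to_csv(
        outdir / "correlations.tsv", sep="\t", index=False, float_format="%.10g"
    )

    with open(outdir / "polarization.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        if res["assortativity"] is not None:
            fh.write(f"assortativity\t{res['assortativity']:.10g}\n")

    with open(outdir / "echo_profile.tsv", "w") as fh:
        fh.write("axis\tdecile\tn_users\tjs_distance\tbootstrap_sd\t"
                 "null_mean\texcess\n")
        for b in res["echo_profile"]:
            fh.write(
                f"{b.axis}\t{b.decile}\t{b.n_users}\t"
                f"{b.js_distance:.10g}\t{b.bootstrap_sd:.10g}\t"
                f"{b.null_mean:.10g}\t{b.excess:.10g}\n"
            )


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline, writing report tables and a manifest.

    On a stage failure a FAILED marker naming the stage is written and the
    error re-raised; partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    manifest: dict = {
        "config": cfg.to_dict(),
        "version": vaxpol.__version__,
        "seed": cfg.generator.seed,
        "counts": {},
    }
    try:
        users, tweets, events = generate_corpus(cfg.generator)
        io.write_tweets(tweets, outdir / "tweets.jsonl")
        io.write_events(events, outdir / "events.tsv")
        with open(outdir / "latent_users.tsv", "w") as fh:
            fh.write("user_id\tlatent_stance\tn_tweets\n")
            for u in users:
                fh.write(f"{u.user_id}\t{u.latent_stance}\t{u.n_tweets}\n")
        manifest["counts"]["users"] = len(users)
        manifest["counts"]["tweets"] = len(tweets)
        manifest["counts"]["events"] = len(events)

        stage = "analyze"
        res = analyze_corpus(tweets, events, cfg)
        manifest["counts"]["profiles"] = len(res["profiles"])
        manifest["counts"]["graph_nodes"] = res["graph_full"].number_of_nodes()
        manifest["counts"]["graph_edges"] = res["graph_full"].number_of_edges()
        manifest["counts"]["strict_nodes"] = res["graph_strict"].number_of_nodes()
        manifest["counts"]["strict_edges"] = res["graph_strict"].number_of_edges()
        manifest["counts"]["unparseable_urls"] = res["n_unparseable_urls"]

        stage = "report"
        _write_reports(res, outdir)

        manifest["checksums"] = {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "FAILED")
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# sweeps


def sweep(cfg: RunConfig, parameter: str, values: Sequence) -> pd.DataFrame:
    """Re-run the analysis over one parameter, sharing the corpus and seed.

    ``parameter`` must be one of min_weight / tweet_threshold /
    profile_threshold.  Returns a long-format table of headline statistics
    per value.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"choose from {SWEEPABLE}")
    users, tweets, events = generate_corpus(cfg.generator)
    rows = []
    for value in values:
        c = RunConfig.from_dict(cfg.to_dict())
        setattr(c, parameter, type(getattr(c, parameter))(value))
        res = analyze_corpus(tweets, events, c)
        g = res["graph_strict"]
        dist = res["stance_distribution"]
        corr = res["correlations"]
        row = {
            "value": value,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "assortativity": res["assortativity"],
            "frac_antivaxx": dist["antivaxx"],
            "frac_provaxx": dist["provaxx"],
            "frac_unassigned": dist["unassigned"],
        }
        at_mw = corr[corr["min_weight"] == c.min_weight]
        for _, r in at_mw.iterrows():
            row[f"r_{r['axes']}"] = r["r"]
        rows.append(row)
    return pd.DataFrame(rows)
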