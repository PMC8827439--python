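"""Assortativity, Fisher intervals, Jensen-Shannon machinery and the echo
profile."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from _oracles import js_distance_oracle
from conftest import mk_tweet
from vaxpol.polarization import (
    echo_profile,
    fisher_interval,
    global_link_distribution,
    js_distance,
    local_link_distribution,
    neighbor_sentiment_correlation,
    stance_assortativity,
)


class TestFisherInterval:
    def test_closed_form_at_r_zero_n_four(self):
        lower, upper = fisher_interval(0.0, 4)
        assert lower == pytest.approx(-np.tanh(1.0), abs=1e-10)
        assert upper == pytest.approx(np.tanh(1.0), abs=1e-10)
        assert upper == pytest.approx(0.76159415595, abs=1e-9)

    def test_bounds_shrink_monotonically_with_n(self):
        widths = [
            fisher_interval(0.3, n)[1] - fisher_interval(0.3, n)[0]
            for n in (5, 10, 50, 500, 5000)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_small_n_is_error(self):
        for n in (0, 2, 3):
            with pytest.raises(ValueError):
                fisher_interval(0.5, n)

    def test_bounds_bracket_r_strictly_for_moderate_r(self):
        lower, upper = fisher_interval(0.9, 10)
        assert lower < 0.9 < upper


class TestStanceAssortativity:
    def test_two_cliques_no_cross_edges_give_one(self):
        g = nx.union(
            nx.relabel_nodes(nx.complete_graph(4), lambda i: f"a{i}"),
            nx.relabel_nodes(nx.complete_graph(4), lambda i: f"p{i}"),
        )
        labels = {n: ("antivaxx" if n.startswith("a") else "provaxx") for n in g}
        assert stance_assortativity(g, labels) == pytest.approx(1.0)

    def test_complete_bipartite_gives_minus_one(self):
        g = nx.complete_bipartite_graph(3, 3)
        labels = {n: ("antivaxx" if n < 3 else "provaxx") for n in g}
        assert stance_assortativity(g, labels) == pytest.approx(-1.0)

    def test_matches_networkx_numeric_assortativity(self):
        rng = np.random.default_rng(0)
        g = nx.gnm_random_graph(60, 200, seed=1)
        labels = {n: ("antivaxx" if rng.random() < 0.4 else "provaxx") for n in g}
        nx.set_node_attributes(
            g, {n: (-1 if labels[n] == "antivaxx" else 1) for n in g}, "s"
        )
        ours = stance_assortativity(g, labels)
        theirs = nx.numeric_assortativity_coefficient(g, "s")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_single_stance_graph_is_error(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError):
            stance_assortativity(g, {n: "provaxx" for n in g})

    def test_edgeless_graph_is_error(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            stance_assortativity(g, {n: "provaxx" for n in g})


class TestNeighborCorrelation:
    def test_identical_endpoint_means_give_r_one(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
        means = {"a": (0.9, 0.1), "b": (0.9, 0.1), "c": (0.5, 0.5),
                 "d": (0.5, 0.5), "e": (0.1, 0.9), "f": (0.1, 0.9)}
        c = neighbor_sentiment_correlation(g, means, ("anti", "anti"))
        assert c.r == pytest.approx(1.0)
        assert c.n == 6

    def test_too_few_observations_is_error(self):
        g = nx.Graph([("a", "b")])
        means = {"a": (0.9, 0.1), "b": (0.2, 0.8)}
        with pytest.raises(ValueError):
            neighbor_sentiment_correlation(g, means)

    def test_zero_variance_axis_is_error(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        means = {u: (0.5, 0.3) for u in "abcd"}
        with pytest.raises(ValueError, match="variance"):
            neighbor_sentiment_correlation(g, means)

    def test_homophilous_corpus_has_positive_anti_anti_negative_pro_anti(self):
        from vaxpol.pipeline import RunConfig, analyze_corpus
        from vaxpol.synthetic import GeneratorConfig, generate_corpus

        cfg = RunConfig(
            generator=GeneratorConfig(n_users=1200, homophily=0.95,
                                      sentiment_concentration=30.0, seed=8),
            n_bootstrap=10,
        )
        _, tweets, events = generate_corpus(cfg.generator)
        res = analyze_corpus(tweets, events, cfg)
        corr = res["correlations"]
        row = corr[(corr["min_weight"] == 1) & (corr["axes"] == "anti-anti")].iloc[0]
        assert row["r"] > 0
        row = corr[(corr["min_weight"] == 1) & (corr["axes"] == "pro-anti")].iloc[0]
        assert row["r"] < 0


class TestJSDistance:
    def test_identical_distributions_give_zero(self):
        assert js_distance([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_half_overlap_hand_value(self):
        # sqrt(0.5*KL((.5,.5)||(.75,.25)) + 0.5*KL((1,0)||(.75,.25)))
        assert js_distance([0.5, 0.5], [1.0, 0.0]) == pytest.approx(
            0.5579230452841438, abs=1e-9
        )

    def test_matches_elementwise_oracle_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            length = int(rng.integers(2, 19))
            p = rng.dirichlet(np.ones(length) * rng.uniform(0.2, 3.0))
            q = rng.dirichlet(np.ones(length) * rng.uniform(0.2, 3.0))
            # sparsify some entries to exercise the 0 log 0 convention
            if rng.random() < 0.5:
                p[rng.integers(length)] = 0.0
                p = p / p.sum()
            assert js_distance(p, q) == pytest.approx(
                js_distance_oracle(p, q), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        p, q = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        assert js_distance(p, q) == pytest.approx(js_distance(q, p), abs=1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            js_distance([0.5, 0.5], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            js_distance([0.6, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError):
            js_distance([1.2, -0.2], [0.5, 0.5])


def _linky_tweets(user, domains, n_tweets=9):
    """n_tweets vaccine tweets whose URLs cover the listed domains."""
    tweets = []
    for i in range(n_tweets):
        urls = [f"https://{d}/x{i}" for d in (domains if i == 0 else [])]
        tweets.append(
            mk_tweet(user=user, p_anti=0.2, p_pro=0.6, urls=urls,
                     tweet_id=f"{user}-{i}")
        )
    return tweets


class TestLocalLinkDistribution:
    VOCAB = ["bbc.com", "youtube.com"]

    def test_single_qualifying_neighbor_gives_indicator(self):
        g = nx.Graph([("f", "n")])
        tweets = _linky_tweets("n", ["youtube.com"] * 6)
        dist = local_link_distribution(g, {"f"}, tweets, self.VOCAB)
        assert dist == pytest.approx([0.0, 1.0])

    def test_neighbor_below_min_urls_excluded(self):
        g = nx.Graph([("f", "n")])
        tweets = _linky_tweets("n", ["youtube.com"] * 4)  # 4 < 5 URLs
        assert local_link_distribution(g, {"f"}, tweets, self.VOCAB) is None

    def test_two_neighbor_pool_hand_count(self):
        g = nx.Graph([("f", "n1"), ("f", "n2")])
        tweets = (
            _linky_tweets("n1", ["youtube.com"] * 3 + ["bbc.com"] * 2)
            + _linky_tweets("n2", ["bbc.com"] * 2 + ["youtube.com"] * 3)
        )
        dist = local_link_distribution(
            g, {"f"}, tweets, ["youtube.com", "bbc.com"]
        )
        assert dist == pytest.approx([0.6, 0.4])

    def test_focal_users_own_links_not_pooled(self):
        g = nx.Graph([("f", "n")])
        tweets = _linky_tweets("n", ["youtube.com"] * 6) + _linky_tweets(
            "f", ["bbc.com"] * 6
        )
        dist = local_link_distribution(g, {"f"}, tweets, self.VOCAB)
        assert dist == pytest.approx([0.0, 1.0])


class TestEchoProfile:
    def test_single_user_bin_has_zero_bootstrap_sd(self):
        g = nx.Graph([("f", "n"), ("g2", "n2")])
        tweets = (
            _linky_tweets("n", ["youtube.com"] * 6)
            + _linky_tweets("n2", ["bbc.com"] * 6)
        )
        bins = {"f": 1}
        prof = echo_profile(
            g, tweets, bins, ["bbc.com", "youtube.com"], n_bootstrap=50, seed=0
        )
        assert len(prof) == 1
        assert prof[0].n_users == 1
        assert prof[0].bootstrap_sd == 0.0

    def test_identical_link_profiles_give_zero_distance(self):
        g = nx.Graph([("f1", "n1"), ("f2", "n2")])
        tweets = _linky_tweets("n1", ["youtube.com"] * 6) + _linky_tweets(
            "n2", ["youtube.com"] * 6
        )
        prof = echo_profile(
            g, tweets, {"f1": 1, "f2": 2}, ["bbc.com", "youtube.com"],
            n_bootstrap=20, seed=0,
        )
        for cell in prof:
            assert cell.js_distance == pytest.approx(0.0, abs=1e-12)

    def test_empty_bins_omitted_with_warning(self):
        g = nx.Graph([("f", "n")])
        tweets = _linky_tweets("n", ["youtube.com"] * 6)
        with pytest.warns(UserWarning, match="omitted"):
            prof = echo_profile(
                g, tweets, {"f": 1, "isolated": 2},
                ["bbc.com", "youtube.com"], n_bootstrap=10, seed=0,
            )
        assert [c.decile for c in prof] == [1]

    def test_fixed_seed_reproduces_bootstrap_sds(self, small_corpus):
        cfg, _, tweets, events = small_corpus
        from vaxpol import network as net
        from vaxpol import stance as stance_mod

        spec = net.WindowSpec(origin=cfg.origin, days=cfg.window_days)
        g = net.aggregate_mmr(net.window_edge_sets(events, spec, cfg.n_windows))
        profiles = stance_mod.attribute_all(tweets)
        vax = [t for t in tweets if t.vaccine_related]
        bins = stance_mod.decile_bin_users(
            [t.p_anti for t in vax],
            {u: p.mean_p_anti for u, p in profiles.items()},
            {u: p.n_vax_tweets for u, p in profiles.items()},
        )
        vocab = list(cfg.vocab)
        p1 = echo_profile(g, tweets, bins, vocab, n_bootstrap=100, seed=11)
        p2 = echo_profile(g, tweets, bins, vocab, n_bootstrap=100, seed=11)
        assert p1 == p2

    def test_global_distribution_requires_qualifying_links(self):
        with pytest.raises(ValueError):
            global_link_distribution(
                _linky_tweets("u", ["bbc.com"]), ["bbc.com"], min_urls=99
            )
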