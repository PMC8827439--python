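# Methods

This note records the models, conventions and numerical choices behind
`vaxpol`, in the order the pipeline runs them, together with what the
synthetic generator does and does not emulate.

## Synthetic corpus generator (`vaxpol.synthetic`)

The generator produces the three inputs the analysis consumes — a tweet
table, an interaction-event table, and (implicitly, through the shipped
category map) a domain vocabulary — with the statistical structure the
analysis assumes. It is first-class, tested code, not a fixture.

**Users and activity.** `n_users` users receive i.i.d. latent stances from
`stance_mix`, default (3% anti, 45% pro, 52% neutral), matching the
observed rarity of consistently anti-vaccine profiles relative to
pro-vaccine ones. Per-user vaccine-tweet counts are discrete lognormal
(default μ=1.3, σ=1.0 on the log scale, capped at 500): a heavy-tailed
stand-in for the "few prolific, many occasional" activity pattern of real
platforms. The true activity law of the emulated corpora is unpublished,
so these defaults are deliberately configurable and should not be read as
empirical estimates.

**Sentiment triples.** Each tweet's (p_anti, p_pro, p_neutral) is drawn
from a Dirichlet with mean shifted toward the author's latent stance
(anti-mean (0.75, 0.10, 0.15), etc.) and precision
`sentiment_concentration` (default 12). This emulates the *output* of an
upstream text classifier without reproducing one: the analysis only ever
consumes probability triples. Large concentrations make per-tweet
evidence nearly deterministic, which is how the label-recovery tests
separate attribution errors from generator noise.

**Interactions and homophily.** Each user holds a Poisson(`interaction_rate`,
default 2.0) set of partners per 91-day window; every realized pair emits
two directed events of the same kind (mention or retweet), making the
stream reciprocal by construction. Partner choice follows a
planted-partition mixture: with probability 2h − 1 the partner is forced
in-group, otherwise uniform over all users. We chose this over the naive
"in-group with probability h" because the naive rule is not stance-blind
at h = 0.5 when groups have unequal sizes (an anti user whose group is 3%
of the population but receives 50% in-group partners is strongly
assortative); the mixture makes h = 0.5 exactly neutral and h = 1 fully
homophilous regardless of the mixture, so the homophily dial has a clean
interpretation at both ends. Between windows, each partner slot is
resampled independently with probability `rewire_rate` (default 0.3),
which produces the geometric-like decay of edge-set Jaccard similarity
with window separation.

**URLs.** Tweets carry Poisson(`url_rate`, default 0.4 — the ratio of
link-bearing to total vaccine tweets in the emulated setting) URLs whose
domains are drawn from the author's stance-conditional distribution over
an 18-domain vocabulary. Default distributions put ~90% of an anti or pro
user's mass on their stance-leaning half of the vocabulary (with overlap
on shared platforms such as youtube.com and facebook.com), and neutral
users skew mainstream.

**Randomness.** All draws flow from one root seed through named
substreams (users / tweets / interactions / urls), so one component can be
regenerated without perturbing the others, and a fixed seed yields
byte-identical corpora.

**What the generator does not emulate.** Tweet text; bot/automation
behavior; the higher per-user activity of anti-vaccine accounts (latent
activity is stance-independent, so the tweet-level anti share tracks the
profile-level share rather than exceeding it); bursty or seasonal
timestamp patterns; URL shorteners (the redirect map is exercised with
synthetic fixtures in tests). Passing tests therefore demonstrate that
the analysis machinery is correct and well-calibrated on corpora with
these statistical features — not that any particular real-world effect
size is reproduced.

## Stance attribution (`vaxpol.stance`)

A profile is antivaxx (provaxx) iff at least `profile_threshold` (default
0.5) of its vaccine-related tweets have p_anti (p_pro) ≥ `tweet_threshold`
(default 0.5). Both thresholds are inclusive. If both rules fire — which
requires tweets sitting exactly on the 0.5/0.5 boundary or genuinely mixed
profiles — the profile is unassigned, keeping the labels mutually
exclusive; the same applies when neither fires. An empty tweet list is an
unassigned profile, not an error. Note one subtlety: raising
`profile_threshold` can *unmask* a label (a profile with frac_anti = 1.0
and frac_pro = 0.6 is unassigned at threshold 0.5 because both rules fire,
but antivaxx at 0.75); the per-axis qualifying sets themselves are
monotone in the threshold.

**Decile binning.** Bin edges are the 10%…90% quantiles of the
*tweet-level* probability distribution; users are then placed by their
*mean* probability into [edge_{k−1}, edge_k) intervals, last bin
right-closed. This tweet-level-edges / user-level-means construction is
kept deliberately even though it concentrates users in middle bins.
Duplicate quantile edges (possible under degenerate inputs) merge the
affected bins with a warning. Users with fewer than `min_tweets`
(default 5) vaccine tweets are excluded before binning.

## MMR network (`vaxpol.network`)

Windows are fixed-length, half-open, consecutive intervals
[origin + kL, origin + (k+1)L), default L = 91 days, anchored at the data
origin (configurable). A window edge {A, B} requires A→B and B→A events of
the *same* kind within the window; `mixed_type_reciprocity=True` gives the
looser any-kind reading. Multi-edges within a window collapse; the
aggregated edge weight counts windows, not events, so 1 ≤ weight ≤
n_windows. Self-events are dropped at ingest with a logged count.

**Weibull degree fit.** Degrees are truncated at 500 before fitting (the
far tail of real interaction graphs is dominated by automated accounts)
and zero degrees excluded. The continuous two-parameter Weibull density
with exp(−(k/α)^β) is fitted by maximum likelihood — scipy's
`weibull_min` MLE with location pinned at 0, polished by a Nelder-Mead
pass on the package's own log-likelihood (tolerances 1e-10) so the fit is
a verified local maximum. Constant degree vectors are rejected.

**Temporal Jaccard.** J(S_i, S_j) on window edge sets, with J = 0 when
both sets are empty (a documented convention; the union is empty and the
similarity of two empty networks carries no signal).

## Link analysis (`vaxpol.links`)

URLs resolve through an offline redirect map (cycle-guarded, misses fall
through), then normalize to a base domain: lowercase, strip scheme,
credentials, port, path, query, fragment and one leading "www.".
Subdomains are otherwise preserved because several well-known sources are
subdomain-identified (articles.mercola.com, go.thetruthaboutvaccines.com);
category lookups try the exact host first and then parent domains.
Unparseable URLs are skipped and counted, never fatal. `base_url` is
idempotent.

Top-domain rankings are per-stance-group counts with lexicographic
tie-breaks (documented, since any tie rule is arbitrary); coverage is the
fraction of a group's links inside its own top-k. Category frequencies
count a multi-category domain toward each category, so rows need not sum
to 1; unmapped domains land in an explicit "uncategorized" column. Links
are counted per tweet occurrence (not deduplicated per user) — the
alternative is a one-line change where `user_domain_counts` is built.

The shipped `data/domain_categories.yaml` covers the most-shared domains
of the vaccine discourse across seven categories (commercial, conspiracy,
news, pseudoscience, science, social_media, youtube).

## Polarization and echo chambers (`vaxpol.polarization`)

**Assortativity.** Discrete stances map to −1/+1 and the statistic is the
Pearson correlation over ordered edge endpoints (each edge contributing
both orientations), which equals Newman's numeric-attribute assortativity
(cross-checked against networkx in tests). Graphs with no edges or a
single represented stance raise rather than returning NaN. The phrase
"correlation between stance and connectedness" admits other readings; the
edge-endpoint correlation is the standard one and the package's default.

**Neighbor-sentiment correlations.** Continuous analogue of the above:
Pearson r between the focal node's mean sentiment on one axis and the
neighbor's on another, over both orientations of every edge, with the
Fisher one-sd interval tanh(arctanh r ± 1/√(n−3)) at n = ordered
observations. A node-vs-neighborhood-mean variant was considered and
rejected as the default because the per-edge version weights users by
degree exactly as the assortativity does, keeping the two statistics
comparable. n ≤ 3 or a zero-variance axis raises.

**Jensen-Shannon distance.** sqrt(½KL(P‖M) + ½KL(Q‖M)), M = ½(P+Q),
base-2 logarithms: 0 iff P = Q, 1 on disjoint supports. Zero-count
entries follow 0·log(0/x) = 0; terms with M = 0 cannot arise where P or Q
is positive. Inputs must be normalized to 1e-9. The implementation
delegates to scipy and is held to 1e-12 agreement with a hand-written
two-KL-term oracle in the tests.

**Echo profile.** For each stance decile: the focal set is the bin's
users; the "region" is their 1-hop neighborhood (radius configurable;
focal users excluded so the signal is exposure, not self-expression);
neighbors must have shared ≥ 5 URLs and posted ≥ 5 vaccine tweets; pooled
counts are restricted to the top-domain vocabulary and normalized. The
point estimate is the JS distance to the global distribution (all
qualifying users). The bootstrap resamples the bin's users with
replacement B = 1000 times, recomputing the pooled local distribution
against the *fixed* global distribution; a single-user bin therefore has
sd exactly 0. Empty bins, and bins whose neighborhoods yield no
qualifying links, are omitted with a warning.

**Null calibration.** Plug-in JS distances of finite pools are biased
away from zero, and the bias depends on the pooled link count: a decile
pooling 100 links sits visibly farther from the global distribution than
one pooling 3000, even when every user draws links from the *same*
distribution. The fluctuations of the plug-in distance are smaller than
these offsets, so raw distances of unequal-size bins are not comparable
at any corpus size. Each `EchoBin` therefore also reports `null_mean` —
the mean distance of 200 multinomial pools of the same total size drawn
from the global distribution itself — and `excess = js_distance −
null_mean` as the bias-adjusted echo signal (≈ 0 when a vicinity shares
typical sources). The multinomial null is exact for the generator (links
are conditionally i.i.d. given stance); on real data with strong per-user
link clustering it is conservative in the sense of under-correcting, and
a user-level parametric null would be the refinement.

## Pipeline (`vaxpol.pipeline`, `vaxpol.cli`)

One `RunConfig` (YAML) reaches every stage parameter; a single root seed
drives generation and bootstrap, making full runs byte-identical — the
manifest records config, per-stage counts and SHA-256 checksums of every
report table, and a stage failure writes a FAILED marker naming the stage
while retaining partial outputs. Reports are plain TSV/CSV: stance and
tweet-sentiment distributions, full and thresholded edge lists, Jaccard
matrix, Weibull parameters, giant-component summary, top domains,
category frequencies, neighbor correlations per minimum edge weight, and
the echo profile on both stance axes. `sweep` re-runs the analysis over
min_weight or either stance threshold on a shared corpus. Figures are
deliberately not produced; the tables are the tested surface.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so each statistic is
well-resolved: mixture recovery at n_users = 10000; the homophily →
assortativity map at n_users = 2000 with 4 windows; echo-profile
separation/flatness at n_users = 8000 (outer stance deciles then pool
hundreds of links, which the 2-sd excess comparisons require); Weibull
recovery on 1e5 samples; the stance-rule census exhaustively for 1–2
tweet profiles on the 0.05 probability grid, exhaustively over
qualifying-class count vectors with boundary-heavy representatives for
3–4 tweets, plus 40k random grid profiles; determinism on a 500-user
smoke configuration.

## Known limitations

- The stance rule's tie-unmasking (above) means label sets are not
  globally monotone in `profile_threshold`.
- Windows are calendar partitions; rolling or overlapping windows are out
  of scope.
- The echo-profile null assumes exchangeable links within the pool; real
  per-user clustering calls for a hierarchical null.
- The generator's stance-independent activity understates tweet-level
  anti shares relative to settings where anti users are hyperactive.
- No live URL crawling: redirect resolution is whatever the offline map
  provides.
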