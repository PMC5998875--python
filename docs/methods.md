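# Methods

## Problem setting

A protein family with a large, surface-rich interaction domain (the
motivating case is the WD40 β-propeller family) is expected to act as a
set of interaction hubs and complex scaffolds. `ppifam` quantifies that
expectation on a confidence-scored PPI network through four statistics —
hub enrichment, k-core localization, hub co-expression, and clique-based
complex prediction — and ships a synthetic generator that plants each of
the corresponding structures so the statistics can be validated end to
end.

## Cleaning and confidence filtering

Raw scored edge rows are cleaned by four rules, each counted in a
provenance record: missing identifiers, self-interactions, non-numeric or
out-of-range scores, and duplicate unordered pairs. Duplicates keep the
**maximum** score: database exports repeat an interaction once per
evidence source, and the strongest evidence is the natural
representative; the choice is deterministic and makes cleaning
idempotent.

The high-confidence cut retains interactions with `score ≥ q`, where `q`
is a quantile (default 0.75) of the score distribution computed by linear
interpolation between order statistics. Because scores in real exports
take few distinct values, thousands of interactions can sit exactly at
the threshold, so the retained fraction generally exceeds `1 − quantile`;
the `≥` comparison keeps all of them. The fraction reporter rounds to the
nearest percent.

Downstream analyses run on the **main component** (largest connected
component; size ties broken by smallest member identifier for
determinism).

## Centralities and enrichment

Betweenness, closeness and clustering use the conventional definitions
(betweenness normalized by `(N−1)(N−2)/2`, the number of node pairs
excluding the node; closeness as the reciprocal mean shortest-path length
to reachable nodes; clustering as the fraction of connected neighbour
pairs). Stress — the count of shortest paths with the node interior, each
unordered endpoint pair counted once — is computed by a Brandes-style
accumulation (`δ(v) = σ(v)·Σ_w (1 + δ(w)/σ(w))` over the shortest-path
DAG) rather than path enumeration, giving `O(N·E)` instead of exponential
cost; the test suite pins it to an explicit path-enumeration oracle on
small graphs.

A hub is a node with degree **strictly greater** than the cutoff
(default 5; 10 and 15 supported for sensitivity). Family enrichment is
the 2×2 odds ratio `(a·d)/(b·c)` over (family × hub) with a χ² test
**with Yates continuity correction** — the corrected statistic is the one
that reproduces the published p-value on the published contingency
counts, which is how the convention was fixed; a zero cell flags the
result as degenerate and a Haldane–Anscombe estimate (0.5 added to each
cell) is reported alongside. Metric comparisons use a one-sided
Mann–Whitney U test (family stochastically greater), exact for small
tie-free samples and tie-corrected asymptotic otherwise, plus the fold
change of medians.

## k-core localization

k-values come from standard iterative peeling. The family percentage at
each `k` is computed over the **cumulative k-core subnetwork** (all nodes
with k-value ≥ k), not the exclusive layer — that is the quantity whose
near-linear rise with `k` signals enrichment toward the global centre;
exclusive layer counts are emitted separately. The trend is an OLS
regression of percentage on `k`; the default range runs from 1 to the
largest `k` whose core retains ≥ 5% of nodes, so the sparse extreme tail
(where percentages are computed over a handful of nodes) does not
dominate the fit. The range is configurable.

## Co-expression

Sample columns are averaged within tissues to give one vector per gene;
all Pearson correlations are computed on these tissue-averaged vectors.
Pairs involving a zero-variance profile are **skipped, not scored 0** —
constant expression carries no correlation information — and hubs left
with no scorable partner are omitted. The null distribution permutes the
profile→protein assignment over all profiled proteins (not only hubs)
and recomputes every hub's average PCC, pooling across shuffles;
reproducible under a seed.

Expression-pattern labels: `high_in_all` (every tissue > 10),
`tissue_specific` (top tissue ≥ 5× every other), `tissue_preferential`
(top ≥ 2× second-highest but fold < 5), `high_in_many` (> 10 in ≥ 75% of
tissues but not all), else `other`, applied in that order. The 2× floor
for "preference" and the 75% quorum for "many" are interpretation
choices with no canonical value; both are parameters.

## Complex prediction and evaluation

Maximal cliques of the family + first-neighbour induced subgraph are
enumerated with Bron–Kerbosch (with pivoting) and returned in sorted
order so `core_<i>` identifiers are stable across runs. Retained cliques
have ≥ 3 members and ≥ 1 family member. Merging replaces any pair with
`|A∩B|/min(|A|,|B|) ≥ t` by its union, scanning pairs in lexicographic
order and iterating to a fixpoint; a single pass would leave
threshold-exceeding pairs created by earlier unions, so fixpoint is the
coherent reading of "iterative merging". Order dependence is possible in
principle; the tests compare the canonical order against an exhaustive
all-orders oracle on small instances. At `t = 1.0` (M10) no merging of
any kind occurs — among maximal cliques no set contains another, so
subset absorption cannot arise.

Matching uses `ω = |A∩B|²/(|A|·|B|)`; a reference complex is matched at
cutoff `c > 0` when some prediction reaches `ω ≥ c`, and at `c = 0` when
any overlap exists. MMR builds the bipartite graph of qualifying pairs
(default cutoff 0.2) weighted by ω and solves the maximum-weight
one-to-one matching exactly as an assignment problem, dividing the
matched weight by the reference count. Decoy complexes are size-matched
uniform samples from the main component, one (configurable) per
prediction, seeded.

## Synthetic generator

The generator emulates the structure the analysis assumes, not any
specific database's literal distributions:

* **Network** — Barabási–Albert preferential attachment with
  `m = mean_degree/2` (default mean degree 8), giving heavy-tailed
  degrees and a connected graph. A `family_fraction` (default 10%) of
  nodes receives extra edges; counts per node are geometric
  (negative-binomial, r = 1) with mean `(boost−1)·2m`, so the expected
  family degree is `boost ×` background while the overdispersed tail
  leaves some family members below any hub cutoff — real protein families
  span near-isolated members to hundred-partner hubs, and a degenerate
  all-family-are-hubs table would make the odds ratio undefined. Extra
  edges attach preferentially by degree, pulling the family toward the
  dense global centre (raising family k-values), as observed for
  scaffold-rich families in real interactomes.
* **Planted complexes** — disjoint member sets (default 20 complexes,
  sizes 4–8, ≥ 1 family member each) fully interconnected, so each is a
  clique of the emitted network and recovery against the truth is
  well-defined.
* **Expression** — every gene mixes a global per-tissue factor
  (weight √0.1 by default) with independent noise; co-complex members
  additionally share a complex factor, with weights set so their total
  expected pairwise correlation is ρ (default 0.8). The global factor
  mirrors the baseline covariation random gene pairs show in real tissue
  panels and gives decoy complexes a small positive co-expression floor,
  as in real data. Standardized signal maps to abundances as
  `50 + 10·z`, clipped at zero (a ~5σ event, leaving correlations
  untouched); each tissue gets 2 replicate samples with small noise.
* **Reference perturbation** — truth complexes with members dropped/added
  at configured rates; the realized ω against the source is recomputable
  in closed form from the emitted sets.

Defaults above are the study conditions used by the recovery tests and
the acceptance script: 2000 nodes, 10% family, 3× boost, 20 planted
complexes, ρ = 0.8, 30 tissues. What passing recovery shows: the pipeline
detects planted hub enrichment, core localization, clique complexes and
co-expression at these effect sizes. What it does not show: robustness to
overlapping complexes, score-correlated noise edges, missing expression
coverage, or identifier-mapping artefacts, none of which the generator
emulates.

## Numerical and degenerate-input choices

* Quantile: linear interpolation (the common statistical default);
  empty interaction sets are an error for the filter ("no scores to
  rank") and valid for the cleaner.
* Betweenness on graphs with < 3 nodes is all zeros; isolated nodes have
  closeness 0; clustering is 0 for degree < 2.
* Constant trend-fit response returns slope 0, R² = 0 rather than a
  degenerate regression.
* All generator and decoy randomness flows through
  `numpy.random.default_rng(seed)`; two runs of the pipeline with the
  same config produce byte-identical TSVs.

## Limitations

* Identifier mapping (UniProt and cross-database) is out of scope; inputs
  must be pre-mapped, and IDs are opaque case-sensitive strings.
* Merging order dependence is only characterized empirically on small
  instances; pathological inputs could make the fixpoint order-sensitive.
* The clique-based predictor is deliberately aggressive (high recall,
  many background cliques); precision-oriented module detectors are not
  reimplemented here.
* Stress and betweenness are exact, not sampled; on networks far larger
  than ~10⁴ nodes the all-pairs stage dominates runtime and can be
  skipped via `compute_path_centralities: false`.
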