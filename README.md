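# ppifam

Family-centric network analysis of scored protein–protein interaction
(PPI) networks, built for the question: *does a given protein family —
e.g. the WD40 β-propeller repeat family — occupy a privileged position in
the interactome, and can that position be exploited to predict the
complexes the family assembles?*

Given a confidence-scored edge list (HIPPIE-style export), a family
membership list, an optional tissue expression matrix and an optional
reference complex set (CORUM-style extract), the pipeline runs:

1. **Cleaning & confidence filtering** — drop self-interactions, rows with
   missing identifiers and invalid scores, merge duplicate unordered pairs
   (keeping the maximum score), then retain interactions scoring at least a
   quantile threshold (default: the third quartile, `score ≥ Q3`).
2. **Topology & hub enrichment** — degree, normalized betweenness
   `C_b(n) = Σ_{s≠n≠t} σ_st(n)/σ_st / [(N−1)(N−2)/2]`, closeness
   `C_c(n) = 1/avg L(m,n)`, stress (shortest paths through `n`), and
   clustering `C_n = 2e_n/(k_n(k_n−1))` on the main component; hubs are
   nodes with degree > cutoff (default 5). Family-vs-rest enrichment is a
   2×2 odds ratio with a continuity-corrected χ² test, plus one-sided
   Mann–Whitney comparisons of each metric.
3. **k-core localization** — iterative peeling assigns each node the
   largest `k` whose k-core contains it; the family share of each k-core
   subnetwork is regressed on `k` to quantify enrichment toward the
   network's dense global centre.
4. **Hub co-expression** — each gene's samples are averaged per tissue;
   a hub's average Pearson correlation (PCC) with its partners separates
   intramodular (complex-assembling) from intermodular hubs, against a
   null that shuffles the profile→protein assignment.
5. **Clique-based complex prediction** — maximal cliques (Bron–Kerbosch)
   of the family + first-neighbour subnetwork, filtered to size ≥ 3 with
   ≥ 1 family member, optionally merged at overlap thresholds 0.5–1.0
   (sets M05…M10; M10 = no merging). Predictions are matched to a
   reference set with the overlap score `ω = |A∩B|²/(|A|·|B|)` and scored
   by the maximal matching ratio (MMR); an expression-based check compares
   each complex's mean pairwise PCC against size-matched random decoys.

A seeded synthetic generator (`ppifam.synthgen`) emulates the assumed data
structure — scale-free topology, a degree-boosted family, planted clique
complexes, latent-factor co-expression — so the whole pipeline is testable
without any database downloads.

## Worked example

Generate a synthetic study and run the full pipeline:

```sh
ppifam simulate --out-dir demo/bundle --n-nodes 2000 --degree-boost 3.0 \
    --n-complexes 20 --rho 0.8 --seed 1
ppifam topology demo/bundle/network.tsv --family demo/bundle/family.txt \
    --out demo/metrics.tsv --skip-path-centralities
```

which prints (seed 1):

```
{"counts": [194, 6, 1267, 533], "odds_ratio": 13.601946856090503,
 "chi2": 63.40232564931891, "p_value": 1.6851893953012942e-15}
```

— 194 of the 200 family proteins exceed the degree-5 hub cutoff against
1267 of 1800 background proteins, an odds ratio of 13.6: the planted 3×
degree boost is recovered as strong hub enrichment. The same bundle
through the complex predictor:

```sh
ppifam complexes --network demo/bundle/network.tsv \
    --family demo/bundle/family.txt --reference demo/bundle/reference.tsv \
    --out demo/predicted.tsv
```

reports 1737 predicted complexes with every planted complex recovered
(`"n_reference_matched": 20, "mmr": 1.0` at every ω cutoff in the
matching table): with noiseless planting, each planted clique survives as
a maximal clique, so ω = 1 against its reference copy.

For a full run from a config file, `ppifam run config.yaml` executes all
stages and writes per-stage TSVs plus `summary.json` (odds ratios,
medians, fold changes, matched counts per cutoff, MMR, co-expression
medians) into the configured output directory.

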