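"""Node centralities, hub classification and family enrichment statistics.

Centralities follow the conventions of the Cytoscape NetworkAnalyzer:

* betweenness  C_b(n) = sum over pairs s != n != t of sigma_st(n)/sigma_st,
  normalised by the number of node pairs excluding n, (N-1)(N-2)/2;
* closeness    C_c(n) = 1 / mean shortest-path length to reachable nodes;
* stress       number of shortest paths with n as an interior node,
  each unordered (s, t) pair counted once;
* clustering   C_n = 2 e_n / (k_n (k_n - 1)), 0 when k_n < 2.

The family-vs-rest comparisons are a 2x2 odds-ratio/chi-square test on the
hub flag and a one-sided Mann-Whitney U test on any per-node metric.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "degree_all",
    "betweenness_all",
    "closeness_all",
    "stress_all",
    "clustering_all",
    "classify_hubs",
    "ContingencyResult",
    "enrichment_odds_ratio",
    "GroupComparison",
    "compare_groups",
]


def degree_all(g: nx.Graph) -> dict[str, int]:
    """Degree of every node (number of direct links)."""
    return dict(g.degree())


def betweenness_all(g: nx.Graph) -> dict[str, float]:
    """Normalised betweenness centrality of every node.

    For undirected graphs the normalisation divisor is (N-1)(N-2)/2; graphs
    with fewer than 3 nodes get all zeros.
    """
    if g.number_of_nodes() < 3:
        return {n: 0.0 for n in g.nodes}
    return nx.betweenness_centrality(g, normalized=True)


def closeness_all(g: nx.Graph) -> dict[str, float]:
    """Closeness: reciprocal of the mean shortest-path length to reachable
    nodes. Isolated nodes get 0."""
    return nx.closeness_centrality(g, wf_improved=False)


def stress_all(g: nx.Graph) -> dict[str, int]:
    """Stress centrality: shortest paths through each node.

    Each unordered source-target pair contributes once; endpoints are not
    counted as lying on their own paths. Computed by Brandes-style
    accumulation: a BFS from each source records shortest-path counts
    (sigma) and predecessors, then a backward sweep accumulates
    delta(v) = sigma(v) * sum over successors w of (1 + delta(w)/sigma(w)),
    the number of source-rooted shortest paths with v interior.
    """
    stress = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        sigma = {s: 1}
        dist = {s: 0}
        pred: dict = {v: [] for v in g.nodes}
        order = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # delta[v] = number of shortest paths from s through interior v
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in pred[w]:
                if v != s:
                    delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
        for v in order:
            if v != s:
                stress[v] += delta[v]
    # every unordered (s, t) pair was visited from both endpoints
    return {v: int(round(x / 2.0)) for v, x in stress.items()}


def clustering_all(g: nx.Graph) -> dict[str, float]:
    """Clustering coefficient C_n = 2 e_n / (k_n (k_n - 1)); 0 if k_n < 2."""
    return nx.clustering(g)


def classify_hubs(
    degrees: Mapping[str, int], cutoff: int = 5
) -> dict[str, bool]:
    """Hub flag per node: hub iff degree strictly greater than the cutoff."""
    if cutoff < 0:
        raise ValueError(f"hub cutoff must be non-negative, got {cutoff}")
    return {n: d > cutoff for n, d in degrees.items()}


@dataclass
class ContingencyResult:
    """2x2 family-by-hub contingency test.

    counts = (family_hub, family_nonhub, other_hub, other_nonhub);
    odds_ratio = (a*d)/(b*c); chi2/p from a chi-square test with Yates
    continuity correction. ``degenerate`` flags a zero cell, in which case
    the odds ratio is inf or nan but the chi-square is still computed.
    """

    counts: tuple[int, int, int, int]
    odds_ratio: float
    chi2: float
    p_value: float
    degenerate: bool = False
    odds_ratio_haldane: float = float("nan")
    """Haldane-Anscombe estimate (0.5 added to every cell): the standard
    finite odds-ratio estimate when a cell is zero."""


def enrichment_odds_ratio(
    hub_flags: Mapping[str, bool], family_flags: Mapping[str, bool]
) -> ContingencyResult:
    """Odds ratio of being a hub for family vs non-family nodes.

    The OR divides the hub:non-hub ratio in the family by the same ratio in
    the rest; significance is a chi-square test with continuity correction
    on the 2x2 table.
    """
    if set(hub_flags) != set(family_flags):
        raise ValueError("hub and family flags must cover the same nodes")
    a = sum(1 for n in hub_flags if family_flags[n] and hub_flags[n])
    b = sum(1 for n in hub_flags if family_flags[n] and not hub_flags[n])
    c = sum(1 for n in hub_flags if not family_flags[n] and hub_flags[n])
    d = sum(1 for n in hub_flags if not family_flags[n] and not hub_flags[n])
    return contingency_from_counts(a, b, c, d)


def contingency_from_counts(
    a: int, b: int, c: int, d: int
) -> ContingencyResult:
    """Build a :class:`ContingencyResult` from explicit 2x2 counts
    (family-hub, family-nonhub, other-hub, other-nonhub)."""
    degenerate = 0 in (a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(a * d, b * c, dtype=float)
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return ContingencyResult(
        counts=(a, b, c, d),
        odds_ratio=float(odds),
        chi2=float(chi2),
        p_value=float(p),
        degenerate=degenerate,
        odds_ratio_haldane=float(haldane),
    )


@dataclass
class GroupComparison:
    """Family-vs-rest comparison of a per-node metric.

    fold_change is the ratio of medians (family / other); p_value is a
    one-sided Mann-Whitney U test of the family being stochastically
    greater.
    """

    median_family: float
    median_other: float
    fold_change: float
    p_value: float
    n_family: int
    n_other: int


def compare_groups(
    values: Mapping[str, float], family_flags: Mapping[str, bool]
) -> GroupComparison:
    """Compare a metric between family and non-family nodes.

    Uses a one-sided Mann-Whitney U test (alternative: family greater),
    exact for small tie-free samples and the tie-corrected normal
    approximation otherwise.
    """
    fam = np.asarray(
        [values[n] for n in values if family_flags[n]], dtype=float
    )
    other = np.asarray(
        [values[n] for n in values if not family_flags[n]], dtype=float
    )
    if fam.size == 0 or other.size == 0:
        raise ValueError("both groups must be non-empty")
    med_f = float(np.median(fam))
    med_o = float(np.median(other))
    fold = med_f / med_o if med_o != 0 else float("inf")
    _, p = stats.mannwhitneyu(fam, other, alternative="greater",
                              method="auto")
    return GroupComparison(
        median_family=med_f,
        median_other=med_o,
        fold_change=fold,
        p_value=float(p),
        n_family=int(fam.size),
        n_other=int(other.size),
    )


def node_metrics_table(
    g: nx.Graph,
    hub_cutoff: int = 5,
    k_values: Mapping[str, int] | None = None,
    include_paths: bool = True,
):
    """Assemble the per-node metrics table as a pandas DataFrame.

    ``include_paths=False`` skips the all-pairs measures (betweenness,
    closeness, stress), which dominate the cost on large graphs.
    """
    import pandas as pd

    deg = degree_all(g)
    hubs = classify_hubs(deg, hub_cutoff)
    clus = clustering_all(g)
    data = {
        "node": list(g.nodes),
        "family": [bool(g.nodes[n].get("family", False)) for n in g.nodes],
        "degree": [deg[n] for n in g.nodes],
        "clustering": [clus[n] for n in g.nodes],
        "is_hub": [hubs[n] for n in g.nodes],
    }
    if include_paths:
        bet = betweenness_all(g)
        clo = closeness_all(g)
        strs = stress_all(g)
        data["betweenness"] = [bet[n] for n in g.nodes]
        data["closeness"] = [clo[n] for n in g.nodes]
        data["stress"] = [strs[n] for n in g.nodes]
    if k_values is not None:
        data["k_value"] = [k_values[n] for n in g.nodes]
    return pd.DataFrame(data)
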