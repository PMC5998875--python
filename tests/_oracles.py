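"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive — subset enumeration, explicit
shortest-path listing, repeated peeling, permutation search — and shares no
code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque


# ---------------------------------------------------------------- cleaning
def dedup_oracle(rows):
    """Distinct valid unordered pairs with max score, by brute force."""
    valid = {}
    for a, b, s in rows:
        if a is None or b is None or str(a).strip() == "" or str(b).strip() == "":
            continue
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            continue
        try:
            score = float(s)
        except (TypeError, ValueError):
            continue
        if not (0.0 <= score <= 1.0):
            continue
        key = tuple(sorted((a, b)))
        valid[key] = max(valid.get(key, 0.0), score)
    return valid


def quantile_oracle(values, q):
    """Linear-interpolation quantile from sorted order statistics."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    pos = q * (len(xs) - 1)
    lo = int(pos)
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


# ------------------------------------------------------------------ graphs
def components_oracle(nodes, edges):
    """Connected components by plain breadth-first search."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    comp.add(w)
                    queue.append(w)
        comps.append(comp)
    return comps


def _all_shortest_paths(adj, s, t):
    """Every shortest s-t path, as node lists, via BFS layering + DFS."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in adj[v]:
            if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def path_centrality_oracle(nodes, edges):
    """Betweenness (normalised), stress and closeness by explicit
    enumeration of every shortest path. Exponential; keep graphs small."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    nodes = list(nodes)
    n = len(nodes)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    closeness = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        interior = [p[1:-1] for p in paths]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in interior if v in p)
            if through:
                betweenness[v] += through / sigma
                stress[v] += through
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        betweenness = {v: x / norm for v, x in betweenness.items()}
    for v in nodes:
        dist = {v: 0}
        queue = deque([v])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        others = [d for u, d in dist.items() if u != v]
        closeness[v] = (1.0 / (sum(others) / len(others))) if others else 0.0
    return betweenness, stress, closeness


def clustering_oracle(nodes, edges):
    """C_n = 2 e_n / (k_n (k_n - 1)) by counting connected neighbour pairs."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        e = sum(
            1
            for x, y in itertools.combinations(sorted(adj[v]), 2)
            if y in adj[x]
        )
        out[v] = 2.0 * e / (k * (k - 1))
    return out


def kcore_oracle(nodes, edges):
    """k-values by literal repeated peeling for k = 1, 2, ..."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    kval = {n: 0 for n in nodes}
    k = 1
    alive = set(nodes)
    while alive:
        # peel nodes of degree < k within the surviving subgraph
        while True:
            doomed = {
                v for v in alive if sum(1 for w in adj[v] if w in alive) < k
            }
            if not doomed:
                break
            alive -= doomed
        for v in alive:
            kval[v] = k
        k += 1
    return kval


def cliques_oracle(nodes, edges):
    """All maximal cliques by enumerating every subset."""
    nodes = sorted(nodes)
    eset = {tuple(sorted(e)) for e in edges}

    def is_clique(sub):
        return all(
            tuple(sorted((a, b))) in eset
            for a, b in itertools.combinations(sub, 2)
        )

    cliques = [
        sub
        for r in range(1, len(nodes) + 1)
        for sub in itertools.combinations(nodes, r)
        if is_clique(sub)
    ]
    maximal = []
    for c in cliques:
        cs = set(c)
        if not any(cs < set(d) for d in cliques):
            maximal.append(c)
    return sorted(maximal)


# -------------------------------------------------------------- statistics
def mannwhitney_exact_oracle(group_a, group_b):
    """Exact one-sided (a greater) Mann-Whitney p by enumerating every
    assignment of the pooled values into groups of the observed sizes."""
    pooled = list(group_a) + list(group_b)
    na = len(group_a)

    def u_stat(a_vals, b_vals):
        u = 0.0
        for x in a_vals:
            for y in b_vals:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    observed = u_stat(group_a, group_b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        a_vals = [pooled[i] for i in idx]
        b_vals = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(a_vals, b_vals) >= observed - 1e-12:
            count += 1
    return observed, count / total


def ols_oracle(x, y):
    """Closed-form simple OLS via the normal equations."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    syy = sum((yi - my) ** 2 for yi in y)
    ss_res = sum(
        (yi - (intercept + slope * xi)) ** 2 for xi, yi in zip(x, y)
    )
    r2 = 1.0 - ss_res / syy if syy > 0 else 0.0
    return slope, intercept, r2


def matching_oracle(weights):
    """Maximum-weight one-to-one matching by trying every assignment.

    ``weights`` is a rows x cols nested list; rows and cols may differ.
    """
    n_rows = len(weights)
    n_cols = len(weights[0]) if n_rows else 0
    best = 0.0
    k = min(n_rows, n_cols)
    for rows in itertools.combinations(range(n_rows), k):
        for cols in itertools.permutations(range(n_cols), k):
            best = max(best, sum(weights[r][c] for r, c in zip(rows, cols)))
    return best


def pcc_oracle(u, v):
    """Pearson correlation from its covariance/sd definition."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = sum((a - mu) ** 2 for a in u) ** 0.5
    sv = sum((b - mv) ** 2 for b in v) ** 0.5
    return cov / (su * sv)
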