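"""Clique-based complex prediction, overlap matching and evaluation.

The predictor mines a family-labelled interaction network in three steps:
extract the subnetwork induced by family proteins and their first-order
neighbours; enumerate all maximal cliques (Bron-Kerbosch); keep cliques of
size > 2 containing at least one family protein. Overlapping cliques can
optionally be merged at a threshold on |A n B| / min(|A|, |B|) — merge sets
are conventionally named M05 (50%) through M10 (100%, no merging).

Predictions are evaluated against a reference complex set with the overlap
score omega = |A n B|^2 / (|A| * |B|): the number of reference complexes
matched at each omega cutoff, and the maximal matching ratio (MMR), the
weight of a maximum one-to-one omega-weighted matching divided by the
reference count. An expression-based check scores each complex by its mean
pairwise PCC and compares against size-matched random decoys.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .coexpr import _standardize

__all__ = [
    "PredictedComplex",
    "ReferenceComplex",
    "MatchReport",
    "ComplexCoexpression",
    "family_neighborhood",
    "maximal_cliques",
    "filter_cliques",
    "merge_cliques",
    "omega",
    "match_reference",
    "mmr",
    "complex_coexpression",
    "generate_decoys",
    "read_complexes",
    "write_complexes",
]


@dataclass(frozen=True)
class PredictedComplex:
    id: str
    members: frozenset
    has_family: bool = True


@dataclass(frozen=True)
class ReferenceComplex:
    id: str
    members: frozenset


@dataclass
class MatchReport:
    """Matching of predictions to the reference set at one omega cutoff."""

    omega_cutoff: float
    n_reference_matched: int
    mmr: float


@dataclass
class ComplexCoexpression:
    complex_id: str
    n_pairs_scored: int
    score: float


def family_neighborhood(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on family nodes and their direct neighbours.

    All induced edges are kept, including neighbour-neighbour edges; those
    close the triangles the clique search depends on.
    """
    family = [n for n, d in g.nodes(data=True) if d.get("family", False)]
    if not family:
        raise ValueError("network contains no family nodes")
    keep = set(family)
    for n in family:
        keep.update(g[n])
    return g.subgraph(keep).copy()


def maximal_cliques(g: nx.Graph) -> list[tuple]:
    """All maximal cliques, in a deterministic order.

    Enumeration is Bron-Kerbosch with pivoting; each clique is returned as
    a sorted member tuple and the list is sorted lexicographically.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques)


def filter_cliques(
    cliques: Iterable[Sequence],
    family_flags: Mapping[str, bool],
    min_size: int = 3,
) -> list[PredictedComplex]:
    """Retain cliques with >= min_size members and >= 1 family member.

    Retained cliques are assigned stable identifiers core_1 ... core_n in
    the deterministic enumeration order.
    """
    out: list[PredictedComplex] = []
    for c in cliques:
        if len(c) < min_size:
            continue
        if not any(family_flags.get(m, False) for m in c):
            continue
        out.append(
            PredictedComplex(
                id=f"core_{len(out) + 1}",
                members=frozenset(c),
                has_family=True,
            )
        )
    return out


def _overlap_fraction(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def merge_cliques(
    complexes: Sequence[PredictedComplex], overlap_threshold: float
) -> list[PredictedComplex]:
    """Iteratively merge complexes overlapping above a threshold.

    Two member sets A, B merge when |A n B| / min(|A|, |B|) >= threshold;
    merging replaces them by their union and repeats until no pair
    qualifies (fixpoint). Pairs are examined in deterministic
    lexicographic order of their sorted member tuples. A threshold of 1.0
    means no merging at all (the M10 convention; among maximal cliques no
    set is a subset of another, so subset absorption cannot arise).

    Merged complexes are re-identified core_1 ... core_n in sorted order.
    """
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap threshold must be in (0, 1]")
    if not complexes:
        return []
    if overlap_threshold >= 1.0:
        return list(complexes)
    sets = sorted({c.members for c in complexes},
                  key=lambda m: tuple(sorted(m)))
    changed = True
    while changed:
        changed = False
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if _overlap_fraction(sets[i], sets[j]) >= overlap_threshold:
                    merged = sets[i] | sets[j]
                    del sets[j]
                    del sets[i]
                    sets.append(merged)
                    sets = sorted(set(sets), key=lambda m: tuple(sorted(m)))
                    changed = True
                    break
            if changed:
                break
    return [
        PredictedComplex(id=f"core_{k + 1}", members=m, has_family=True)
        for k, m in enumerate(sets)
    ]


def omega(a: frozenset | set, b: frozenset | set) -> float:
    """Overlap score |A n B|^2 / (|A| * |B|) in [0, 1].

    1 iff the sets are identical, 0 iff disjoint.
    """
    if not a or not b:
        raise ValueError("omega is undefined for empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def _omega_matrix(
    reference: Sequence[ReferenceComplex],
    predicted: Sequence[PredictedComplex],
) -> np.ndarray:
    w = np.zeros((len(reference), len(predicted)))
    for i, r in enumerate(reference):
        for j, p in enumerate(predicted):
            w[i, j] = omega(r.members, p.members)
    return w


def mmr(
    predicted: Sequence[PredictedComplex],
    reference: Sequence[ReferenceComplex],
    omega_cutoff: float = 0.2,
) -> float:
    """Maximal matching ratio at an omega cutoff.

    Builds the bipartite graph of (reference, predicted) pairs with omega
    >= cutoff, weights edges by omega, solves the maximum-weight one-to-one
    matching exactly (assignment problem), and divides the matched weight
    by the number of reference complexes.
    """
    if not predicted or not reference:
        raise ValueError("both complex sets must be non-empty")
    w = _omega_matrix(reference, predicted)
    w = np.where(w >= omega_cutoff, w, 0.0) if omega_cutoff > 0 else w
    if not w.any():
        return 0.0
    rows, cols = linear_sum_assignment(w, maximize=True)
    total = float(w[rows, cols].sum())
    return total / len(reference)


def match_reference(
    predicted: Sequence[PredictedComplex],
    reference: Sequence[ReferenceComplex],
    cutoffs: Sequence[float] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
) -> list[MatchReport]:
    """Reference complexes matched by any prediction at each omega cutoff.

    A reference complex counts as matched at cutoff c > 0 when some
    predicted complex reaches omega >= c; at c = 0 any positive overlap
    counts. Each report also carries the MMR at that cutoff.
    """
    if not predicted or not reference:
        raise ValueError("both complex sets must be non-empty")
    w = _omega_matrix(reference, predicted)
    reports = []
    for c in cutoffs:
        if c > 0:
            matched = int((w.max(axis=1) >= c).sum())
            wc = np.where(w >= c, w, 0.0)
        else:
            matched = int((w.max(axis=1) > 0).sum())
            wc = w
        if wc.any():
            rows, cols = linear_sum_assignment(wc, maximize=True)
            ratio = float(wc[rows, cols].sum()) / len(reference)
        else:
            ratio = 0.0
        reports.append(MatchReport(float(c), matched, ratio))
    return reports


def complex_coexpression(
    complexes: Sequence[PredictedComplex | ReferenceComplex],
    profiles: pd.DataFrame,
) -> list[ComplexCoexpression]:
    """Mean pairwise PCC over each complex's profiled members.

    Pairs involving a missing or zero-variance profile are skipped;
    complexes with fewer than 2 scorable members are omitted.
    """
    z, row_of = _standardize(profiles)
    t = z.shape[1]
    out: list[ComplexCoexpression] = []
    for cx in complexes:
        rows = [
            row_of[m]
            for m in sorted(cx.members)
            if m in row_of and not np.isnan(z[row_of[m], 0])
        ]
        if len(rows) < 2:
            continue
        zs = z[rows]
        corr = (zs @ zs.T) / (t - 1)
        iu = np.triu_indices(len(rows), k=1)
        vals = corr[iu]
        out.append(
            ComplexCoexpression(
                complex_id=cx.id,
                n_pairs_scored=int(vals.size),
                score=float(vals.mean()),
            )
        )
    return out


def generate_decoys(
    predicted: Sequence[PredictedComplex],
    node_pool: Sequence[str],
    seed: int | None = None,
    n_per_complex: int = 1,
) -> list[PredictedComplex]:
    """Size-matched random decoy complexes drawn from a node pool.

    For every predicted complex, ``n_per_complex`` decoys of the same size
    are sampled uniformly without replacement from the pool (the main
    component's nodes). Reproducible under the seed.
    """
    pool = sorted(set(node_pool))
    sizes = [len(p.members) for p in predicted]
    if sizes and max(sizes) > len(pool):
        raise ValueError("node pool smaller than the largest complex")
    rng = np.random.default_rng(seed)
    decoys = []
    for p in predicted:
        for r in range(n_per_complex):
            members = rng.choice(pool, size=len(p.members), replace=False)
            decoys.append(
                PredictedComplex(
                    id=f"decoy_{p.id}_{r + 1}",
                    members=frozenset(members.tolist()),
                    has_family=False,
                )
            )
    return decoys


def read_complexes(
    path: str | Path, id_column: int = 0, member_start: int = 1
) -> list[ReferenceComplex]:
    """Read a one-complex-per-line TSV: ``id<TAB>member1<TAB>member2...``.

    ``id_column``/``member_start`` allow CORUM-style extracts with extra
    leading columns to be mapped without reformatting.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            members = frozenset(m for m in fields[member_start:] if m)
            if members:
                out.append(ReferenceComplex(fields[id_column], members))
    return out


def write_complexes(
    complexes: Sequence[PredictedComplex | ReferenceComplex],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for cx in complexes:
            fh.write("\t".join([cx.id, *sorted(cx.members)]) + "\n")
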