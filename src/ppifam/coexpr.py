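"""Tissue-averaged expression, hub co-expression and expression patterns.

Expression inputs are a genes x samples abundance matrix (FPKM or any
non-negative unit) and a sample-to-tissue map. Samples from the same tissue
are averaged, giving each gene one vector with one component per tissue;
all Pearson correlations (PCCs) are computed on these tissue-averaged
vectors.

A hub's average PCC with its interaction partners separates constitutive
("intramodular", high average PCC — complex-assembling) hubs from
context-specific ("intermodular", low average PCC) ones. The null for this
statistic shuffles the profile-to-protein assignment and recomputes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_profiles",
    "read_expression_matrix",
    "read_sample_map",
    "pcc",
    "hub_average_pcc",
    "shuffled_null",
    "classify_pattern",
    "HubCoexpression",
]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV: first column gene ID, rest samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>tissue map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "tissue"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["tissue"]))


def build_profiles(
    matrix: pd.DataFrame, sample_tissue_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average each gene's abundances within tissues.

    Returns a genes x tissues DataFrame (tissues sorted by name). Every
    sample column must be mapped to a tissue; an unmapped sample raises a
    ``ValueError`` naming it. At least two tissues are required.
    """
    unmapped = [c for c in matrix.columns if c not in sample_tissue_map]
    if unmapped:
        raise ValueError(f"samples not mapped to a tissue: {unmapped}")
    tissues = sorted(set(sample_tissue_map[c] for c in matrix.columns))
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    groups = matrix.T.groupby(
        [sample_tissue_map[c] for c in matrix.columns]
    ).mean()
    return groups.T[tissues]


def pcc(u: np.ndarray, v: np.ndarray) -> float:
    """Sample Pearson correlation between two equal-length vectors.

    Requires length >= 3 and nonzero variance in both vectors; a
    zero-variance vector makes the correlation undefined and raises — the
    caller's policy is to skip such pairs.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 3:
        raise ValueError("vectors must be 1-D, equal length >= 3")
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(np.corrcoef(u, v)[0, 1])


def _standardize(profiles: pd.DataFrame) -> tuple[np.ndarray, dict[str, int]]:
    """Rows standardized to zero mean / unit sample-sd (ddof=1).

    Zero-variance rows become all-NaN so any dot product involving them is
    NaN and the pair is skipped. Returns the matrix and a gene -> row map.
    """
    x = profiles.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[(sd == 0).ravel(), :] = np.nan
    index = {g: i for i, g in enumerate(profiles.index)}
    return z, index


@dataclass
class HubCoexpression:
    """Average PCC between a hub and its profiled interaction partners."""

    hub: str
    family: bool
    n_partners_scored: int
    average_pcc: float


def _hub_averages(
    g: nx.Graph,
    hubs: Iterable[str],
    z: np.ndarray,
    row_of: Mapping[str, int],
) -> list[tuple[str, int, float]]:
    t = z.shape[1]
    out = []
    for hub in hubs:
        i = row_of.get(hub)
        if i is None or np.isnan(z[i, 0]):
            continue
        vals = []
        for partner in g[hub]:
            j = row_of.get(partner)
            if j is None or np.isnan(z[j, 0]):
                continue
            vals.append(float(z[i] @ z[j]) / (t - 1))
        if vals:
            out.append((hub, len(vals), float(np.mean(vals))))
    return out


def hub_average_pcc(
    g: nx.Graph,
    hub_flags: Mapping[str, bool],
    profiles: pd.DataFrame,
) -> list[HubCoexpression]:
    """Average PCC over each hub's scorable partners.

    Partners without an expression profile, and pairs involving a
    zero-variance profile, are skipped rather than scored 0 (constant
    expression carries no correlation information). Hubs with no scorable
    partner, or no profile themselves, are omitted.
    """
    hubs = sorted(n for n, h in hub_flags.items() if h)
    z, row_of = _standardize(profiles)
    results = _hub_averages(g, hubs, z, row_of)
    return [
        HubCoexpression(
            hub=h,
            family=bool(g.nodes[h].get("family", False)),
            n_partners_scored=n,
            average_pcc=avg,
        )
        for h, n, avg in results
    ]


def shuffled_null(
    g: nx.Graph,
    hub_flags: Mapping[str, bool],
    profiles: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of hub average PCCs under profile shuffling.

    Each shuffle permutes the profile-to-protein assignment over all
    proteins that have profiles (not only hubs), recomputes every hub's
    average PCC, and pools the values across shuffles.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    hubs = sorted(n for n, h in hub_flags.items() if h)
    z, row_of = _standardize(profiles)
    genes = sorted(set(row_of) & set(g.nodes))
    pooled: list[float] = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(genes))
        shuffled_map = {
            genes[i]: row_of[genes[perm[i]]] for i in range(len(genes))
        }
        for _, _, avg in _hub_averages(g, hubs, z, shuffled_map):
            pooled.append(avg)
    return np.asarray(pooled, dtype=float)


def classify_pattern(
    profile: np.ndarray | pd.Series,
    high_cutoff: float = 10.0,
    fold_cutoff: float = 5.0,
    many_fraction: float = 0.75,
    preference_floor: float = 2.0,
) -> str:
    """Classify a tissue-averaged profile into an expression pattern.

    * ``high_in_all``: every component > high_cutoff;
    * ``tissue_specific``: the top tissue is >= fold_cutoff times every
      other tissue;
    * ``tissue_preferential``: a preferred tissue exists (top >=
      preference_floor x second-highest) but the fold is below fold_cutoff;
    * ``high_in_many``: > high_cutoff in at least ``many_fraction`` of
      tissues but not all;
    * ``other`` otherwise.

    The rules are checked in that order; each gene gets exactly one label.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("profile needs at least 2 tissues")
    n_high = int((x > high_cutoff).sum())
    if n_high == x.size:
        return "high_in_all"
    order = np.sort(x)[::-1]
    top, second = order[0], order[1]
    if top > 0 and top >= fold_cutoff * second:
        return "tissue_specific"
    if top > 0 and top >= preference_floor * second:
        return "tissue_preferential"
    if n_high >= many_fraction * x.size:
        return "high_in_many"
    return "other"
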