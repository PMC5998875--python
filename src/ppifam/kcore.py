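"""k-core decomposition and family enrichment toward the global centre.

The k-core of a graph is the maximal induced subgraph of minimum degree k,
obtained by iteratively removing nodes of degree < k. A node's k-value
(its layer) is the largest k whose core still contains it; larger k-values
sit closer to the dense global centre of the network, so comparing the
family's k-values against the rest asks whether the family concentrates
near that centre rather than merely having many links.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .topology import GroupComparison, compare_groups

__all__ = [
    "kcore_decompose",
    "family_core_profile",
    "layer_table",
    "core_trend_fit",
    "TrendFit",
]


def kcore_decompose(g: nx.Graph) -> dict[str, int]:
    """k-value (layer index) of every node.

    Self-loops are disallowed by construction upstream; the decomposition
    is the standard iterative peeling.
    """
    return nx.core_number(g)


def family_core_profile(
    assignments: Mapping[str, int], family_flags: Mapping[str, bool]
) -> tuple[pd.DataFrame, GroupComparison | None]:
    """Family share of each k-core subnetwork plus a k-value comparison.

    For each k from 1 to the degeneracy, the k-core subnetwork consists of
    all nodes with k-value >= k (cumulative membership, not the exclusive
    layer); the profile reports the percentage of family nodes among them.
    Also returns the family-vs-rest comparison of k-values (medians, fold
    change, one-sided Mann-Whitney p), or None when one group is empty.
    """
    nodes = list(assignments)
    if not nodes:
        raise ValueError("no core assignments")
    kmax = max(assignments.values())
    rows = []
    for k in range(1, kmax + 1):
        in_core = [n for n in nodes if assignments[n] >= k]
        n_fam = sum(1 for n in in_core if family_flags[n])
        n_tot = len(in_core)
        rows.append(
            {
                "k": k,
                "n_family": n_fam,
                "n_total": n_tot,
                "percentage": 100.0 * n_fam / n_tot if n_tot else np.nan,
            }
        )
    profile = pd.DataFrame(rows)
    n_fam = sum(1 for n in nodes if family_flags[n])
    if 0 < n_fam < len(nodes):
        comparison = compare_groups(dict(assignments), dict(family_flags))
    else:
        comparison = None
    return profile, comparison


def layer_table(
    assignments: Mapping[str, int], family_flags: Mapping[str, bool]
) -> pd.DataFrame:
    """Exclusive-layer counts: nodes whose k-value equals k exactly.

    One row per layer, descending k, with the family members of the layer
    listed by ID.
    """
    kmax = max(assignments.values())
    rows = []
    for k in range(kmax, -1, -1):
        layer = sorted(n for n, kv in assignments.items() if kv == k)
        fam = [n for n in layer if family_flags[n]]
        rows.append(
            {
                "k": k,
                "n_family": len(fam),
                "n_other": len(layer) - len(fam),
                "family_members": ",".join(fam),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """OLS fit of family percentage on k over a chosen k range."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    k_range: tuple[int, int]


def default_k_range(profile: pd.DataFrame, min_core_fraction: float = 0.05
                    ) -> tuple[int, int]:
    """Default regression range: k = 1 up to the largest k whose core still
    retains at least ``min_core_fraction`` of all nodes."""
    n_total = int(profile.loc[profile["k"] == 1, "n_total"].iloc[0])
    eligible = profile[profile["n_total"] >= min_core_fraction * n_total]
    return (1, int(eligible["k"].max()))


def core_trend_fit(
    profile: pd.DataFrame, k_range: tuple[int, int] | None = None
) -> TrendFit:
    """Linear regression of the family percentage on k.

    An almost-linear rise of the family share with k is the signature of
    enrichment toward the global centre. Requires at least 3 points in the
    chosen range.
    """
    if k_range is None:
        k_range = default_k_range(profile)
    lo, hi = k_range
    sel = profile[(profile["k"] >= lo) & (profile["k"] <= hi)].dropna(
        subset=["percentage"]
    )
    if len(sel) < 3:
        raise ValueError("need at least 3 points for the trend fit")
    x = sel["k"].to_numpy(dtype=float)
    y = sel["percentage"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        # constant response: zero slope, no explained variance
        return TrendFit(0.0, float(y[0]), 0.0, 1.0, (lo, hi))
    fit = stats.linregress(x, y)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        k_range=(lo, hi),
    )
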