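"""Reading, cleaning and filtering of scored interaction data.

A scored interactome export (HIPPIE-style) is a three-column table of
undirected protein-protein interactions with a confidence score in [0, 1].
This module cleans such tables (self-interactions, missing identifiers,
duplicate unordered pairs), applies the quantile-based high-confidence
filter, and builds family-labelled :class:`networkx.Graph` objects on which
all downstream analyses run.

Protein identifiers are treated as opaque, case-sensitive strings; any
UniProt/accession mapping is assumed to have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Interaction",
    "InteractionSet",
    "load_interactions",
    "read_edge_list",
    "write_edge_list",
    "read_family_list",
    "filter_high_confidence",
    "build_network",
    "main_component",
]


@dataclass(frozen=True)
class Interaction:
    """A cleaned, undirected scored interaction.

    Endpoints are stored in sorted order so that the unordered pair
    (a, b) and (b, a) compare equal.
    """

    id_a: str
    id_b: str
    score: float

    def __post_init__(self) -> None:
        if self.id_a > self.id_b:
            object.__setattr__(self, "id_a", self.id_b)
            object.__setattr__(self, "id_b", self.id_a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class InteractionSet:
    """A deduplicated collection of interactions plus cleaning provenance.

    ``provenance`` counts the raw rows dropped by each cleaning rule, so the
    cleaning step is auditable: keys are ``n_input``, ``n_missing_id``,
    ``n_self``, ``n_bad_score``, ``n_duplicate`` and ``n_kept``.
    """

    interactions: list[Interaction] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    def scores(self) -> np.ndarray:
        return np.asarray([i.score for i in self.interactions], dtype=float)

    def pairs(self) -> set[tuple[str, str]]:
        return {i.pair for i in self.interactions}


def _is_missing(value) -> bool:
    return value is None or str(value).strip() == ""


def load_interactions(records: Iterable[Sequence]) -> InteractionSet:
    """Clean raw scored-edge rows into an :class:`InteractionSet`.

    Cleaning rules, each counted in provenance:

    * rows with an empty/missing identifier are dropped;
    * self-interactions are dropped;
    * rows whose score is non-numeric or outside [0, 1] are dropped;
    * duplicate unordered pairs are merged, keeping the maximum score
      (the strongest evidence for the interaction).

    An empty input yields a valid empty set.
    """
    best: dict[tuple[str, str], float] = {}
    prov = {
        "n_input": 0,
        "n_missing_id": 0,
        "n_self": 0,
        "n_bad_score": 0,
        "n_duplicate": 0,
        "n_kept": 0,
    }
    for row in records:
        prov["n_input"] += 1
        a, b, raw_score = row[0], row[1], row[2]
        if _is_missing(a) or _is_missing(b):
            prov["n_missing_id"] += 1
            continue
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            prov["n_self"] += 1
            continue
        try:
            score = float(raw_score)
        except (TypeError, ValueError):
            prov["n_bad_score"] += 1
            continue
        if not (0.0 <= score <= 1.0) or not np.isfinite(score):
            prov["n_bad_score"] += 1
            continue
        pair = (a, b) if a < b else (b, a)
        if pair in best:
            prov["n_duplicate"] += 1
            best[pair] = max(best[pair], score)
        else:
            best[pair] = score
    interactions = [
        Interaction(a, b, s) for (a, b), s in sorted(best.items())
    ]
    prov["n_kept"] = len(interactions)
    return InteractionSet(interactions, prov)


def read_edge_list(path: str | Path) -> InteractionSet:
    """Read a 3-column TSV edge list (``id_a<TAB>id_b<TAB>score``).

    Lines starting with ``#`` are skipped. A header line is detected by a
    non-numeric third field and skipped.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed edge-list line: {line!r}")
            if first:
                first = False
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header
            rows.append((fields[0], fields[1], fields[2]))
    return load_interactions(rows)


def write_edge_list(s: InteractionSet, path: str | Path) -> None:
    """Write the set back out in the same TSV dialect (with header)."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for i in s.interactions:
            fh.write(f"{i.id_a}\t{i.id_b}\t{i.score:g}\n")


def read_family_list(path: str | Path) -> list[str]:
    """Read a family-membership list: one protein ID per line."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    return ids


def filter_high_confidence(
    s: InteractionSet, quantile: float = 0.75
) -> tuple[InteractionSet, float]:
    """Keep interactions scoring at least the given quantile of all scores.

    The threshold is the stated quantile of the score distribution (linear
    interpolation between order statistics); retention uses ``score >=
    threshold``, so score ties at the threshold can push the retained
    fraction above ``1 - quantile`` — with a third-quartile cut the
    high-confidence set may exceed 25% of the input, as seen in real
    interactome exports where thousands of interactions share the
    threshold score.

    Returns the filtered set and the threshold. Raises ``ValueError`` on an
    empty input ("no scores to rank").
    """
    if len(s) == 0:
        raise ValueError("no scores to rank: interaction set is empty")
    if not (0.0 <= quantile <= 1.0):
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    scores = s.scores()
    threshold = float(np.quantile(scores, quantile))
    kept = [i for i in s.interactions if i.score >= threshold]
    prov = dict(s.provenance)
    prov["n_before_confidence_filter"] = len(s)
    prov["n_kept"] = len(kept)
    return InteractionSet(kept, prov), threshold


def retained_percent(n_retained: int, n_total: int) -> int:
    """Retained fraction as a nearest-percent integer (e.g. 29 for 29%)."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    return int(round(100.0 * n_retained / n_total))


def build_network(
    s: InteractionSet, family_ids: Iterable[str]
) -> nx.Graph:
    """Build a simple undirected graph with a boolean ``family`` node flag.

    Family IDs absent from the network are recorded under
    ``g.graph["family_ids_absent"]`` rather than added as isolated nodes.
    """
    g = nx.Graph()
    for i in s.interactions:
        g.add_edge(i.id_a, i.id_b, score=i.score)
    family = set(family_ids)
    for node in g.nodes:
        g.nodes[node]["family"] = node in family
    g.graph["family_ids_absent"] = sorted(family - set(g.nodes))
    return g


def family_flags(g: nx.Graph) -> dict[str, bool]:
    """Per-node family flag of a labelled graph."""
    return {n: bool(d.get("family", False)) for n, d in g.nodes(data=True)}


def main_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member ID so the
    result is deterministic. The occupation fraction (nodes in the main
    component over all nodes) is stored under
    ``g.graph["main_component_occupation"]``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot take main component of an empty graph")
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    main = components[0]
    sub = g.subgraph(main).copy()
    sub.graph["main_component_occupation"] = len(main) / g.number_of_nodes()
    return sub
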