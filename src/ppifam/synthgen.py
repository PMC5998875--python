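"""Seeded generators for networks, planted complexes and expression data.

Real inputs for this kind of analysis are a scored interactome export, a
family membership list, a tissue expression matrix and a curated complex
set. The generators here emulate their statistical structure so the whole
pipeline is testable end to end without downloads:

* a preferential-attachment (scale-free) background network with a minority
  "family" whose members receive extra edges, raising their expected degree
  by a configurable boost factor;
* planted complexes embedded as cliques, each containing at least one
  family member — ground truth for the clique-based predictor;
* a latent-factor expression model in which members of the same planted
  complex share a per-tissue factor with mixing weight sqrt(rho), so the
  expected pairwise Pearson correlation within a complex is rho while
  unrelated genes are independent;
* reference sets derived from the truth by random member drop/add, with
  the realised overlap score computable in closed form.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cliquepred import ReferenceComplex

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "plant_complexes",
    "generate_expression",
    "perturb_reference",
    "write_bundle",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated bundle, for assertions downstream."""

    seed: int
    family_ids: set = field(default_factory=set)
    planted_complexes: list = field(default_factory=list)  # list[frozenset]
    family_degree_boost: float = 1.0
    within_complex_rho: float = 0.0
    n_tissues: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "family_ids": sorted(self.family_ids),
                "planted_complexes": [
                    sorted(c) for c in self.planted_complexes
                ],
                "family_degree_boost": self.family_degree_boost,
                "within_complex_rho": self.within_complex_rho,
                "n_tissues": self.n_tissues,
            },
            indent=1,
        )


def _node_name(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def generate_network(
    n_nodes: int = 2000,
    mean_degree: float = 8.0,
    family_fraction: float = 0.1,
    family_degree_boost: float = 3.0,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free background network with a degree-boosted family.

    The background is a Barabasi-Albert preferential-attachment graph with
    m = mean_degree / 2 edges per arriving node (heavy-tailed degrees,
    connected by construction). A ``family_fraction`` of nodes is then
    designated the family; each family node gains a geometrically
    distributed number of extra edges (mean (boost - 1) * 2m, so the
    expected family degree is about boost times the background mean), with
    targets drawn preferentially by degree — extra family interactions
    therefore attach to the already-dense centre, as family members of a
    real interactome do, rather than to uniformly random periphery nodes.
    The geometric (overdispersed) spread mirrors the broad degree range of
    real protein families, whose members run from near-isolated to
    hundred-partner hubs, and keeps the family/hub contingency table
    non-degenerate.
    """
    if n_nodes < 20:
        raise ValueError("need at least 20 nodes")
    if family_degree_boost < 1:
        raise ValueError("degree boost must be >= 1")
    m = max(1, int(round(mean_degree / 2)))
    if family_degree_boost * 2 * m > n_nodes - 1:
        raise ValueError("boost would require degree above n - 1")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(
        n_nodes, m, seed=int(rng.integers(2**31))
    )
    width = len(str(n_nodes - 1))
    mapping = {i: _node_name(i, width) for i in base.nodes}
    g = nx.relabel_nodes(base, mapping)
    nodes = sorted(g.nodes)
    n_family = max(1, int(round(family_fraction * n_nodes)))
    family = set(
        rng.choice(nodes, size=n_family, replace=False).tolist()
    )
    base_degree = np.array([g.degree(v) for v in nodes], dtype=float)
    weights = base_degree / base_degree.sum()
    extra_mean = (family_degree_boost - 1.0) * 2 * m
    p_nb = 1.0 / (1.0 + extra_mean)  # negative binomial r=1, mean extra_mean
    for node in sorted(family):
        n_extra = int(rng.negative_binomial(1, p_nb)) if extra_mean > 0 else 0
        if n_extra == 0:
            continue
        # oversample, then drop self/existing-edge targets
        raw = rng.choice(nodes, size=min(4 * n_extra + 8, len(nodes)),
                         replace=False, p=weights)
        added = 0
        for v in raw:
            if v != node and not g.has_edge(node, v):
                g.add_edge(node, v)
                added += 1
                if added == n_extra:
                    break
    for node in g.nodes:
        g.nodes[node]["family"] = node in family
    truth = SyntheticTruth(
        seed=seed,
        family_ids=family,
        family_degree_boost=family_degree_boost,
    )
    return g, truth


def plant_complexes(
    g: nx.Graph,
    truth: SyntheticTruth,
    n_complexes: int = 20,
    size_range: tuple[int, int] = (4, 8),
    family_member_min: int = 1,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Embed disjoint clique complexes with family participation.

    Each complex draws ``family_member_min`` members from the family and
    the rest from unused non-family nodes, then all internal edges are
    added so the complex is a clique in the emitted network. Disjointness
    keeps the planted truth unambiguous for recovery tests.
    """
    lo, hi = size_range
    if lo < 3:
        raise ValueError("complex sizes must be >= 3")
    rng = np.random.default_rng(seed)
    family_pool = sorted(truth.family_ids)
    other_pool = sorted(set(g.nodes) - truth.family_ids)
    rng.shuffle(family_pool)
    rng.shuffle(other_pool)
    planted: list[frozenset] = []
    fi = oi = 0
    for _ in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        n_fam = min(family_member_min, size)
        if fi + n_fam > len(family_pool) or oi + size - n_fam > len(other_pool):
            raise ValueError("not enough unused nodes to plant complexes")
        members = family_pool[fi : fi + n_fam] + other_pool[oi : oi + size - n_fam]
        fi += n_fam
        oi += size - n_fam
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j])
        planted.append(frozenset(members))
    truth.planted_complexes = planted
    return g, truth


def generate_expression(
    node_ids,
    truth: SyntheticTruth,
    n_tissues: int = 30,
    within_complex_rho: float = 0.8,
    noise_sd: float = 1.0,
    samples_per_tissue: int = 2,
    sample_noise_sd: float = 0.1,
    seed: int = 0,
    baseline: float = 50.0,
    amplitude: float = 10.0,
    global_rho: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Latent-factor expression matrix with within-complex correlation.

    Every gene mixes a global per-tissue factor h (weight sqrt(global_rho))
    with independent noise, emulating the baseline covariation that random
    gene pairs show in real tissue panels; members of the same planted
    complex additionally share a complex factor f, with weights chosen so
    their total expected pairwise correlation is rho:

        member:     z = sqrt(g) * h + sqrt(rho - g) * f + sqrt(1 - rho) * eps
        non-member: z = sqrt(g) * h + sqrt(1 - g) * eps

    (g = global_rho; rho below g falls back to the global level). The
    standardized signal is mapped to a non-negative abundance scale as
    baseline + amplitude * z (clipped at 0; with the defaults the clip is
    ~5 sigma out and PCCs are unaffected). Each tissue gets
    ``samples_per_tissue`` replicate samples around the tissue value,
    emulating a multi-sample expression study.

    Returns the genes x samples matrix and the sample -> tissue map.
    """
    if not (0.0 <= within_complex_rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    if not (0.0 <= global_rho < 1.0):
        raise ValueError("global_rho must be in [0, 1)")
    if n_tissues < 3:
        raise ValueError("need at least 3 tissues")
    rng = np.random.default_rng(seed)
    genes = sorted(node_ids)
    idx = {gene: i for i, gene in enumerate(genes)}
    h = rng.normal(0.0, noise_sd, size=n_tissues)
    z = (
        np.sqrt(global_rho) * h
        + np.sqrt(1 - global_rho)
        * rng.normal(0.0, noise_sd, size=(len(genes), n_tissues))
    )
    w_complex = np.sqrt(max(within_complex_rho - global_rho, 0.0))
    w_noise = np.sqrt(1 - max(within_complex_rho, global_rho))
    for cx in truth.planted_complexes:
        f = rng.normal(0.0, noise_sd, size=n_tissues)
        for gene in sorted(cx):
            if gene in idx:
                eps = rng.normal(0.0, noise_sd, size=n_tissues)
                z[idx[gene]] = (
                    np.sqrt(global_rho) * h + w_complex * f + w_noise * eps
                )
    tissue_values = np.clip(baseline + amplitude * z, 0.0, None)
    tissues = [f"tissue{t + 1:02d}" for t in range(n_tissues)]
    columns: dict[str, np.ndarray] = {}
    sample_map: dict[str, str] = {}
    for t, tissue in enumerate(tissues):
        for r in range(samples_per_tissue):
            name = f"{tissue}_s{r + 1}"
            noise = rng.normal(0.0, sample_noise_sd, size=len(genes))
            columns[name] = np.clip(tissue_values[:, t] + noise, 0.0, None)
            sample_map[name] = tissue
    matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    truth.n_tissues = n_tissues
    truth.within_complex_rho = within_complex_rho
    return matrix, sample_map


def perturb_reference(
    truth: SyntheticTruth,
    drop_fraction: float = 0.0,
    add_fraction: float = 0.0,
    node_pool=None,
    seed: int = 0,
) -> list[ReferenceComplex]:
    """Reference set derived from the planted truth by member drop/add.

    Each truth complex is copied; each member is dropped with probability
    ``drop_fraction`` and extra members (``add_fraction`` of the original
    size, rounded) are drawn from ``node_pool``. A perturbation that would
    empty a complex is resampled. The realised overlap score against the
    source is |kept|^2 / (|source| * |perturbed|), recomputable from the
    emitted sets.
    """
    if not (0.0 <= drop_fraction < 1.0 and 0.0 <= add_fraction < 1.0):
        raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for i, cx in enumerate(truth.planted_complexes):
        members = sorted(cx)
        while True:
            kept = [m for m in members if rng.random() >= drop_fraction]
            if kept:
                break
        n_add = int(round(add_fraction * len(members)))
        if n_add > 0:
            pool = sorted(set(node_pool or []) - set(members))
            if pool:
                kept += rng.choice(pool, size=min(n_add, len(pool)),
                                   replace=False).tolist()
        out.append(ReferenceComplex(f"ref_{i + 1}", frozenset(kept)))
    return out


def write_bundle(
    out_dir: str | Path,
    g: nx.Graph,
    truth: SyntheticTruth,
    matrix: pd.DataFrame | None = None,
    sample_map: dict[str, str] | None = None,
    reference: list[ReferenceComplex] | None = None,
    score: float = 0.9,
) -> dict[str, str]:
    """Write a bundle in the exact formats the pipeline consumes.

    Emits the scored edge list (all edges at a constant confidence score),
    the family list, optional expression matrix + sample map, optional
    reference complexes, and the truth JSON. Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    edge_path = out / "network.tsv"
    with open(edge_path, "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\t{score:g}\n")
    paths["network"] = str(edge_path)
    fam_path = out / "family.txt"
    fam_path.write_text("\n".join(sorted(truth.family_ids)) + "\n")
    paths["family"] = str(fam_path)
    if matrix is not None:
        expr_path = out / "expression.tsv"
        matrix.to_csv(expr_path, sep="\t")
        paths["expression"] = str(expr_path)
        map_path = out / "samples.tsv"
        with open(map_path, "w") as fh:
            for sample, tissue in sample_map.items():
                fh.write(f"{sample}\t{tissue}\n")
        paths["sample_map"] = str(map_path)
    if reference is not None:
        ref_path = out / "reference.tsv"
        with open(ref_path, "w") as fh:
            for cx in reference:
                fh.write("\t".join([cx.id, *sorted(cx.members)]) + "\n")
        paths["reference"] = str(ref_path)
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    paths["truth"] = str(truth_path)
    return paths
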