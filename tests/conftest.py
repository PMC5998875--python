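"""Shared fixtures: small hand-built graphs and seeded synthetic bundles."""

from __future__ import annotations

import networkx as nx
import pytest

from ppifam import netio, synthgen


def make_graph(edges, family=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    fam = set(family)
    for n in g.nodes:
        g.nodes[n]["family"] = n in fam
    return g


@pytest.fixture
def path_graph():
    return make_graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star_graph():
    return make_graph([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def four_cycle():
    return make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Full synthetic study: 2000 nodes, 10% family with a 3x degree boost,
    20 planted clique complexes, rho = 0.8 expression over 30 tissues.

    Session-scoped; used by the end-to-end recovery tests.
    """
    seed = 20180424
    g, truth = synthgen.generate_network(
        n_nodes=2000,
        mean_degree=8.0,
        family_fraction=0.1,
        family_degree_boost=3.0,
        seed=seed,
    )
    g, truth = synthgen.plant_complexes(
        g, truth, n_complexes=20, size_range=(4, 8), seed=seed + 1
    )
    matrix, sample_map = synthgen.generate_expression(
        g.nodes, truth, n_tissues=30, within_complex_rho=0.8, seed=seed + 2
    )
    reference = synthgen.perturb_reference(truth, seed=seed + 3)
    out = tmp_path_factory.mktemp("bundle")
    paths = synthgen.write_bundle(out, g, truth, matrix, sample_map, reference)
    return {
        "graph": g,
        "truth": truth,
        "matrix": matrix,
        "sample_map": sample_map,
        "reference": reference,
        "paths": paths,
        "family_flags": netio.family_flags(g),
    }
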