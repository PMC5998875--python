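"""Clique prediction, merging, omega matching, MMR and decoys."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppifam import cliquepred
from ppifam.cliquepred import PredictedComplex, ReferenceComplex

from conftest import make_graph, random_graph
from _oracles import cliques_oracle, matching_oracle


def P(i, *members):
    return PredictedComplex(f"core_{i}", frozenset(members))


def R(i, *members):
    return ReferenceComplex(f"ref_{i}", frozenset(members))


class TestFamilyNeighborhood:
    def test_induced_edges_kept(self):
        g = make_graph([("F", "A"), ("F", "B"), ("A", "B"), ("A", "X")],
                       family=["F"])
        # X is A's neighbour but not F's: excluded
        sub = cliquepred.family_neighborhood(g)
        assert set(sub.nodes) == {"F", "A", "B"}
        assert sub.number_of_edges() == 3

    def test_isolated_family_node_kept(self):
        g = make_graph([("A", "B")], family=[])
        g.add_node("F", family=True)
        sub = cliquepred.family_neighborhood(g)
        assert set(sub.nodes) == {"F"}

    def test_no_family_rejected(self):
        with pytest.raises(ValueError):
            cliquepred.family_neighborhood(make_graph([("A", "B")]))

    def test_node_set_equals_adjacency_union_oracle(self):
        g = random_graph(80, 0.06, 13)
        fam = sorted(g.nodes)[:8]
        for n in g.nodes:
            g.nodes[n]["family"] = n in fam
        sub = cliquepred.family_neighborhood(g)
        expected = set(fam) | {
            w for f in fam for w in g[f]
        }
        assert set(sub.nodes) == expected


class TestMaximalCliques:
    def test_triangle_and_square(self):
        tri = make_graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert cliquepred.maximal_cliques(tri) == [("a", "b", "c")]
        square = make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert cliquepred.maximal_cliques(square) == [
            ("a", "b"), ("a", "d"), ("b", "c"), ("c", "d")
        ]

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_subset_enumeration_on_seeded_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        g = random_graph(n, 0.5, seed)
        assert cliquepred.maximal_cliques(g) == cliques_oracle(
            list(g.nodes), list(g.edges)
        )

    def test_deterministic_order(self):
        g = random_graph(12, 0.5, 5)
        assert cliquepred.maximal_cliques(g) == cliquepred.maximal_cliques(g)


class TestFilterCliques:
    def test_size_and_family_rules(self):
        flags = {"F": True, "a": False, "b": False, "c": False}
        cliques = [("F", "a"), ("a", "b", "c"), ("F", "a", "b")]
        out = cliquepred.filter_cliques(cliques, flags)
        assert [c.members for c in out] == [frozenset({"F", "a", "b"})]
        assert out[0].id == "core_1"

    def test_planted_cliques_all_retained(self, study_bundle):
        truth = study_bundle["truth"]
        g = study_bundle["graph"]
        sub = cliquepred.family_neighborhood(g)
        cliques = cliquepred.maximal_cliques(sub)
        predicted = cliquepred.filter_cliques(
            cliques, study_bundle["family_flags"]
        )
        clique_sets = {c.members for c in predicted}
        # every planted complex is contained in some retained clique
        for planted in truth.planted_complexes:
            assert any(planted <= c for c in clique_sets)


class TestMergeCliques:
    def test_simple_merge(self):
        out = cliquepred.merge_cliques(
            [P(1, "a", "b", "c"), P(2, "a", "b", "d")], 0.5
        )
        assert [c.members for c in out] == [frozenset("abcd")]

    def test_disjoint_unchanged(self):
        cx = [P(1, "a", "b", "c"), P(2, "x", "y", "z")]
        out = cliquepred.merge_cliques(cx, 0.5)
        assert {c.members for c in out} == {c.members for c in cx}

    def test_threshold_one_is_no_merging(self):
        cx = [P(1, "a", "b", "c"), P(2, "a", "b", "d")]
        assert cliquepred.merge_cliques(cx, 1.0) == cx

    def test_chain_fixpoint_matches_order_exhaustive_oracle(self):
        """On the 3-chain instance every merge order reaches the same
        fixpoint, and the canonical order agrees with it."""
        inputs = [frozenset("abc"), frozenset("bcd"), frozenset("def")]
        threshold = 0.6

        def exhaustive(sets):
            results = set()

            def step(current):
                pairs = [
                    (i, j)
                    for i, j in itertools.combinations(range(len(current)), 2)
                    if len(current[i] & current[j])
                    / min(len(current[i]), len(current[j]))
                    >= threshold
                ]
                if not pairs:
                    results.add(frozenset(current))
                    return
                for i, j in pairs:
                    merged = [
                        s for k, s in enumerate(current) if k not in (i, j)
                    ] + [current[i] | current[j]]
                    step(merged)

            step(list(sets))
            return results

        oracle_outcomes = exhaustive(inputs)
        assert len(oracle_outcomes) == 1  # order independent here
        ours = cliquepred.merge_cliques(
            [PredictedComplex(f"c{i}", s) for i, s in enumerate(inputs)],
            threshold,
        )
        assert frozenset(c.members for c in ours) in oracle_outcomes

    @given(st.integers(0, 100), st.sampled_from([0.5, 0.6, 0.8, 1.0]))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_idempotent_and_unions_of_inputs(self, seed, threshold):
        rng = np.random.default_rng(seed)
        pool = "abcdefghij"
        cx = []
        for i in range(int(rng.integers(1, 7))):
            size = int(rng.integers(3, 6))
            members = frozenset(
                rng.choice(list(pool), size=size, replace=False).tolist()
            )
            cx.append(PredictedComplex(f"c{i}", members))
        once = cliquepred.merge_cliques(cx, threshold)
        twice = cliquepred.merge_cliques(once, threshold)
        assert {c.members for c in twice} == {c.members for c in once}
        inputs = [c.members for c in cx]
        for merged in once:
            covering = [s for s in inputs if s <= merged.members]
            assert frozenset().union(*covering) == merged.members


class TestOmega:
    def test_identity_disjoint_and_closed_form(self):
        a = frozenset("abcde")
        assert cliquepred.omega(a, a) == 1.0
        assert cliquepred.omega(a, frozenset("xyz")) == 0.0
        assert cliquepred.omega(frozenset("abcd"), frozenset("abcxyz")) == (
            pytest.approx(9 / 24)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cliquepred.omega(frozenset(), frozenset("a"))

    @given(
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
    )
    @settings(derandomize=True, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        w = cliquepred.omega(a, b)
        assert 0.0 <= w <= 1.0
        assert w == cliquepred.omega(b, a)
        assert (w == 1.0) == (a == b)
        assert (w == 0.0) == (not a & b)


class TestMatchReference:
    def test_identical_single_complex(self):
        pred = [P(1, "a", "b", "c")]
        ref = [R(1, "a", "b", "c")]
        for report in cliquepred.match_reference(pred, ref):
            assert report.n_reference_matched == 1
            assert report.mmr == pytest.approx(1.0)

    def test_no_overlap(self):
        reports = cliquepred.match_reference(
            [P(1, "a", "b", "c")], [R(1, "x", "y", "z")]
        )
        assert all(r.n_reference_matched == 0 for r in reports)
        assert all(r.mmr == 0.0 for r in reports)

    def test_counts_match_pairwise_omega_brute_force(self):
        rng = np.random.default_rng(17)
        pool = [f"p{i}" for i in range(40)]
        ref = [
            R(i, *rng.choice(pool, size=5, replace=False)) for i in range(6)
        ]
        pred = []
        for i, r in enumerate(ref):
            members = set(r.members)
            members.discard(sorted(members)[0])
            members.add(f"extra{i}")
            pred.append(P(i, *members))
        cutoffs = [0.0, 0.2, 0.5, 0.8, 1.0]
        reports = cliquepred.match_reference(pred, ref, cutoffs)
        for c, report in zip(cutoffs, reports):
            expected = 0
            for r in ref:
                best = max(cliquepred.omega(r.members, p.members)
                           for p in pred)
                expected += (best >= c) if c > 0 else (best > 0)
            assert report.n_reference_matched == expected

    def test_matched_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(23)
        pool = [f"p{i}" for i in range(30)]
        ref = [R(i, *rng.choice(pool, 4, replace=False)) for i in range(8)]
        pred = [P(i, *rng.choice(pool, 5, replace=False)) for i in range(10)]
        counts = [
            r.n_reference_matched
            for r in cliquepred.match_reference(pred, ref)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMmr:
    def test_perfect_and_empty(self):
        assert cliquepred.mmr([P(1, "a", "b", "c")],
                              [R(1, "a", "b", "c")]) == 1.0
        assert cliquepred.mmr([P(1, "a", "b", "c")],
                              [R(1, "x", "y", "z")]) == 0.0

    def test_three_by_three_matches_exhaustive_matching(self):
        rng = np.random.default_rng(31)
        pool = [f"p{i}" for i in range(20)]
        ref = [R(i, *rng.choice(pool, 4, replace=False)) for i in range(3)]
        pred = [P(i, *rng.choice(pool, 4, replace=False)) for i in range(3)]
        for cutoff in (0.0, 0.1, 0.3):
            weights = [
                [
                    w if (w := cliquepred.omega(r.members, p.members))
                    >= cutoff else 0.0
                    for p in pred
                ]
                for r in ref
            ]
            expected = matching_oracle(weights) / len(ref)
            assert cliquepred.mmr(pred, ref, cutoff) == pytest.approx(expected)

    def test_one_to_one_constraint_binds(self):
        # one prediction overlapping both references can match only one
        pred = [P(1, "a", "b", "c", "d")]
        ref = [R(1, "a", "b", "c", "d"), R(2, "a", "b", "c", "d")]
        assert cliquepred.mmr(pred, ref, 0.2) == pytest.approx(0.5)


class TestComplexCoexpression:
    def test_shared_profile_scores_one(self):
        import pandas as pd

        prof = pd.DataFrame(
            {f"t{i}": [v, v, v] for i, v in enumerate([1.0, 5.0, 2.0])},
            index=["a", "b", "c"],
        )
        out = cliquepred.complex_coexpression([P(1, "a", "b", "c")], prof)
        assert out[0].score == pytest.approx(1.0)
        assert out[0].n_pairs_scored == 3

    def test_mean_of_pairwise_pccs(self):
        rng = np.random.default_rng(3)
        import pandas as pd

        x = rng.normal(size=(3, 10))
        prof = pd.DataFrame(x, index=["a", "b", "c"],
                            columns=[f"t{i}" for i in range(10)])
        out = cliquepred.complex_coexpression([P(1, "a", "b", "c")], prof)
        expected = np.mean(
            [np.corrcoef(x[i], x[j])[0, 1]
             for i, j in [(0, 1), (0, 2), (1, 2)]]
        )
        assert out[0].score == pytest.approx(expected)

    def test_underprofiled_complex_omitted(self):
        import pandas as pd

        prof = pd.DataFrame(
            np.random.default_rng(0).normal(size=(1, 5)),
            index=["a"], columns=[f"t{i}" for i in range(5)]
        )
        assert cliquepred.complex_coexpression([P(1, "a", "b", "c")],
                                               prof) == []


class TestDecoys:
    def test_sizes_preserved_and_deterministic(self):
        pred = [P(1, *"abc"), P(2, *"abcde"), P(3, *"abcdefg")]
        pool = [f"n{i}" for i in range(30)]
        d1 = cliquepred.generate_decoys(pred, pool, seed=4)
        d2 = cliquepred.generate_decoys(pred, pool, seed=4)
        assert [len(d.members) for d in d1] == [3, 5, 7]
        assert [d.members for d in d1] == [d.members for d in d2]
        assert all(d.members <= set(pool) for d in d1)

    def test_pool_equal_to_size_returns_pool(self):
        pred = [P(1, *"abc")]
        d = cliquepred.generate_decoys(pred, ["x", "y", "z"], seed=0)
        assert d[0].members == frozenset({"x", "y", "z"})

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            cliquepred.generate_decoys([P(1, *"abcd")], ["x", "y"], seed=0)


class TestComplexIo:
    def test_round_trip(self, tmp_path):
        pred = [P(1, "b", "a", "c"), P(2, "x", "y", "z")]
        path = tmp_path / "complexes.tsv"
        cliquepred.write_complexes(pred, path)
        back = cliquepred.read_complexes(path)
        assert [(c.id, c.members) for c in back] == [
            ("core_1", frozenset("abc")), ("core_2", frozenset("xyz"))
        ]
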