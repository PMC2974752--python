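import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import as_str, random_graph
from mipalm.modularity import SubnetworkState, delta_lq_alpha
from mipalm.network_io import ComplexCatalog
from mipalm.search import (
    density_score,
    grow_seed,
    merge_complexes,
    overlap_score,
    run_mipalm,
    tune_parameters,
)
from mipalm.topology import TriangleSeed, enumerate_triangles, rank_seeds, weight_all_edges


def seed_of(members) -> TriangleSeed:
    return TriangleSeed(tuple(sorted(members)), 0.0)


class TestGrowSeed:
    def test_isolated_clique_recovered_exactly(self):
        # K6 whose members touch nothing else, beside a disjoint sparse
        # background.  The background must carry enough edges for the gain
        # (1/m)(m_vS - d_v*d_S/(2*sqrt(m))) of the 4th clique node to be
        # positive (3 > 75/(2*sqrt(m)), i.e. m > 156): the expected-edge
        # penalty at alpha=0.5 is global even though the score is local.
        g = as_str(nx.complete_graph(6))
        clique = set(g.nodes)
        bg = nx.relabel_nodes(nx.gnp_random_graph(100, 0.045, seed=8), lambda i: f"bg{i}")
        g = nx.union(g, bg)
        assert g.number_of_edges() > 156
        for tri_seed in [sorted(clique)[:3], sorted(clique)[2:5]]:
            state = grow_seed(g, seed_of(tri_seed), alpha=0.5)
            assert set(state.members) == clique

    def test_seed_with_all_negative_neighbors_stops_immediately(self):
        # Triangle attached to a hub whose degree makes its gain negative
        g = nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("a", "h")])
        g.add_edges_from(("h", f"x{i}") for i in range(12))
        g.add_edges_from((f"x{i}", f"x{i+1}") for i in range(11))
        state = grow_seed(g, seed_of({"a", "b", "c"}), alpha=0.0)
        assert set(state.members) == {"a", "b", "c"}

    def test_whole_k4_absorbed_at_alpha_one(self, k4):
        state = grow_seed(k4, seed_of(["n00", "n01", "n02"]), alpha=1.0)
        assert set(state.members) == set(k4.nodes)

    def test_non_triangle_seed_rejected(self, k4):
        g = k4.copy()
        g.add_edge("n00", "x")
        with pytest.raises(ValueError, match="triangle"):
            grow_seed(g, seed_of({"n00", "n01", "x"}), alpha=0.5)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("gseed", range(4))
    def test_stop_condition_certificate(self, alpha, gseed):
        g = random_graph(40, 0.15, gseed)
        tris = enumerate_triangles(g)
        if not tris:
            pytest.skip("no triangle in this draw")
        state = grow_seed(g, seed_of(tris[0]), alpha)
        if state.neighbors:
            worst = max(delta_lq_alpha(g, v, state) for v in state.neighbors)
            assert worst < 0

    def test_lq_alpha_non_decreasing_along_growth(self):
        from mipalm.modularity import lq_alpha, update_deltas_after_merge

        g = random_graph(30, 0.25, 5)
        tris = enumerate_triangles(g)
        state = SubnetworkState.from_members(g, set(tris[0]), 0.6)
        prev = lq_alpha(g, set(state.members), 0.6)
        while state.neighbors:
            best = max(state.delta_cache.values())
            if best < 0:
                break
            v_star = min(v for v, d in state.delta_cache.items() if d == best)
            state = update_deltas_after_merge(state, v_star)
            cur = lq_alpha(g, set(state.members), 0.6)
            assert cur >= prev - 1e-12
            prev = cur


class TestOverlapScore:
    def test_identical_sets(self):
        assert overlap_score({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert overlap_score({"a"}, {"b"}) == 0.0

    def test_partial(self):
        s = {"x", "y", "z", "u", "v"}
        t = {"x", "y", "z", "p", "q", "r", "m", "n"}
        assert overlap_score(s, t) == pytest.approx(0.6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(set(), {"a"})

    @settings(derandomize=True, max_examples=50)
    @given(
        st.frozensets(st.sampled_from("abcdefgh"), min_size=1),
        st.frozensets(st.sampled_from("abcdefgh"), min_size=1),
    )
    def test_bounds_and_symmetry(self, s, t):
        x = overlap_score(s, t)
        assert 0.0 <= x <= 1.0
        assert x == overlap_score(t, s)
        assert (x == 1.0) == (s <= t or t <= s)


class TestMergeComplexes:
    def test_merges_above_half(self):
        out = merge_complexes([{"a", "b", "c", "d"}, {"b", "c", "d", "e"}])
        assert out == [frozenset("abcde")]

    def test_boundary_half_not_merged(self):
        out = merge_complexes([{"a", "b", "c", "d"}, {"c", "d", "e", "f"}])
        assert len(out) == 2

    def test_disjoint_unchanged(self):
        sets = [frozenset("abc"), frozenset("def"), frozenset("ghi")]
        assert sorted(merge_complexes(sets), key=sorted) == sorted(sets, key=sorted)

    def test_transitive_chain_collapses(self):
        # b-c overlap pulls the chain together once the first union happens
        chain = [{"a", "b", "c"}, {"b", "c", "d"}, {"c", "d", "e"}]
        out = merge_complexes(chain)
        assert out == [frozenset("abcde")]

    @settings(derandomize=True, max_examples=30)
    @given(
        st.permutations(
            [
                frozenset("abcd"), frozenset("bcde"), frozenset("wxyz"),
                frozenset("xyz"), frozenset("mnop"),
            ]
        )
    )
    def test_order_independence_and_fixed_point(self, sets):
        out = merge_complexes(sets)
        assert out == merge_complexes(sorted(sets, key=sorted))
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert overlap_score(out[i], out[j]) <= 0.5


class TestDensityScore:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_clique(self, n):
        g = as_str(nx.complete_graph(n))
        assert density_score(g, set(g.nodes)) == pytest.approx(n)

    def test_four_cycle(self):
        g = as_str(nx.cycle_graph(4))
        assert density_score(g, set(g.nodes)) == pytest.approx(8 / 3)

    def test_tree_on_five(self):
        g = as_str(nx.star_graph(4))
        assert density_score(g, set(g.nodes)) == pytest.approx(2.0)

    def test_singleton_rejected(self, k4):
        with pytest.raises(ValueError):
            density_score(k4, {"n00"})


class TestRunMipalm:
    @pytest.fixture
    def two_k5_and_tree(self):
        g = nx.union(
            nx.relabel_nodes(nx.complete_graph(5), lambda i: f"p{i}"),
            nx.relabel_nodes(nx.complete_graph(5), lambda i: f"q{i}"),
        )
        tree = nx.relabel_nodes(nx.random_labeled_tree(50, seed=4), lambda i: f"t{i:02d}")
        return nx.union(g, tree)

    def test_two_planted_cliques(self, two_k5_and_tree):
        result = run_mipalm(two_k5_and_tree, alpha=0.5, delta=0.0)
        got = sorted(result.member_sets, key=sorted)
        assert got == [
            frozenset(f"p{i}" for i in range(5)),
            frozenset(f"q{i}" for i in range(5)),
        ]

    def test_delta_above_max_kills_everything(self, two_k5_and_tree):
        n_max = two_k5_and_tree.number_of_nodes()
        result = run_mipalm(two_k5_and_tree, alpha=0.5, delta=n_max + 1)
        assert len(result) == 0

    def test_triangle_free_network(self):
        g = as_str(nx.cycle_graph(8))
        result = run_mipalm(g, alpha=0.5, delta=0.0)
        assert len(result) == 0

    def test_output_contract(self):
        g = random_graph(60, 0.12, 9)
        delta = 1.5
        result = run_mipalm(g, alpha=0.4, delta=delta)
        for c in result.complexes:
            assert c.n_s > 3
            assert c.delta_s >= delta
            assert c.delta_s == pytest.approx(density_score(g, c.members))
        sets = result.member_sets
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert overlap_score(sets[i], sets[j]) <= 0.5

    def test_deterministic_across_runs(self):
        g = random_graph(50, 0.15, 2)
        r1 = run_mipalm(g, alpha=0.6, delta=1.0)
        r2 = run_mipalm(g, alpha=0.6, delta=1.0)
        assert r1.member_sets == r2.member_sets
        assert [c.delta_s for c in r1.complexes] == [c.delta_s for c in r2.complexes]


class TestTuneParameters:
    def test_constant_objective_returns_origin(self):
        # triangle-free network: zero predictions, F = 0 over the whole grid
        g = as_str(nx.cycle_graph(10))
        gold = ComplexCatalog([("C1", frozenset({"n00", "n01", "n02"}))])
        alpha, delta, f = tune_parameters(g, gold, coarse_step=0.25, fine_step=0.05)
        assert (alpha, delta, f) == (0.0, 0.0, 0.0)

    def test_recovers_planted_optimum(self, two_k3):
        g = nx.union(
            nx.relabel_nodes(nx.complete_graph(5), lambda i: f"p{i}"),
            nx.relabel_nodes(nx.complete_graph(5), lambda i: f"q{i}"),
        )
        gold = ComplexCatalog([
            ("P", frozenset(f"p{i}" for i in range(5))),
            ("Q", frozenset(f"q{i}" for i in range(5))),
        ])
        alpha, delta, f = tune_parameters(g, gold, coarse_step=0.1, fine_step=0.05)
        assert f == 1.0

    def test_empty_gold_rejected(self, k4):
        with pytest.raises(ValueError):
            tune_parameters(k4, ComplexCatalog([]))
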