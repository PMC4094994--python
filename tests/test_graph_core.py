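"""Modularity, its inversion, and the structural/partition metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import networkx as nx
from modgen import (
    InputError,
    FeasibilityError,
    Partition,
    SimpleGraph,
    average_path_length,
    block_densities,
    clustering_coefficient,
    degree_assortativity,
    expected_modularity,
    modularity,
    partition_jaccard,
    q_max,
    solve_mean_within_degree,
    variation_of_information,
)
from modgen.fixtures import bridged_triangles, disjoint_cliques

from oracles import (
    brute_modularity,
    brute_pair_counts,
    brute_vi,
    random_simple_graph,
)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


class TestModularity:
    def test_single_module_partition_is_exactly_zero(self, rng):
        for _ in range(5):
            edges = random_simple_graph(12, 0.4, rng)
            if not edges:
                continue
            g = SimpleGraph.from_edges(12, edges)
            assert modularity(g, Partition.single(12)) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("k, size", [(2, 3), (3, 4), (4, 5), (6, 3)])
    def test_disjoint_cliques_reach_q_max(self, k, size):
        g, p = disjoint_cliques(k, size)
        assert modularity(g, p) == pytest.approx(1 - 1 / k, abs=1e-12)

    def test_bridged_triangles_closed_form(self):
        g, p = bridged_triangles()
        assert modularity(g, p) == pytest.approx(5 / 14, abs=1e-12)

    def test_agrees_with_brute_force_and_networkx(self, rng):
        for trial in range(30):
            n = int(rng.integers(5, 30))
            edges = random_simple_graph(n, 0.3, rng)
            if not edges:
                continue
            k = int(rng.integers(1, 5))
            labels = rng.integers(1, k + 1, size=n)
            labels[: k] = np.arange(1, k + 1)  # keep labels contiguous
            g = SimpleGraph.from_edges(n, edges)
            p = Partition(labels)
            q = modularity(g, p)
            assert q == pytest.approx(brute_modularity(n, edges, labels), abs=1e-12)
            communities = [set(np.flatnonzero(labels == lab)) for lab in range(1, k + 1)]
            communities = [c for c in communities if c]
            q_nx = nx.community.modularity(g.to_networkx(), communities)
            assert q == pytest.approx(q_nx, abs=1e-12)

    def test_empty_edge_set_is_an_error(self):
        g = SimpleGraph.from_edges(3, [])
        with pytest.raises(InputError):
            modularity(g, Partition.single(3))

    def test_partition_size_mismatch_is_an_error(self):
        g = SimpleGraph.from_edges(3, [(0, 1)])
        with pytest.raises(InputError):
            modularity(g, Partition.single(4))


# ---------------------------------------------------------------------------
# expected modularity and its inversion
# ---------------------------------------------------------------------------


class TestExpectedModularity:
    def test_all_within_reduces_to_q_max(self):
        for k in (2, 4, 10):
            val = expected_modularity(6.0, [30] * k, 6.0, 30 * k)
            assert val == pytest.approx(1 - 1 / k, abs=1e-12)

    def test_equal_sizes_reduction(self):
        # E[Q] = dw/d - 1/K for equal module sizes
        assert expected_modularity(7.0, [200] * 10, 10.0, 2000) == pytest.approx(
            0.6, abs=1e-12
        )

    def test_single_module_is_zero(self):
        assert expected_modularity(5.0, [100], 5.0, 100) == pytest.approx(0.0, abs=1e-12)

    def test_solver_example_from_bisection_oracle(self):
        # bisection on expected_modularity as the independent route
        sizes = [20] * 10
        lo, hi = 0.0, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if expected_modularity(mid, sizes, 10.0, 200) < 0.6:
                lo = mid
            else:
                hi = mid
        assert solve_mean_within_degree(0.6, 10.0, sizes) == pytest.approx(lo, abs=1e-9)
        assert solve_mean_within_degree(0.6, 10.0, sizes) == pytest.approx(7.0, abs=1e-9)

    def test_zero_target_gives_d_over_k(self):
        assert solve_mean_within_degree(0.0, 10.0, [50] * 5) == pytest.approx(2.0)

    def test_boundary_target_gives_full_within(self):
        sizes = [25] * 4
        top = 1 - sum((s / 100) ** 2 for s in sizes)
        assert solve_mean_within_degree(top - 1e-9, 8.0, sizes) == pytest.approx(
            8.0, abs=1e-6
        )

    @given(
        st.integers(2, 8),
        st.floats(2.0, 20.0),
        st.floats(-0.05, 0.7),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_roundtrip_through_expected_modularity(self, k, d_mean, q):
        sizes = [25] * k
        share = sum((s / (25 * k)) ** 2 for s in sizes)
        if not (-share < q < 1 - share - 1e-9):
            return
        dw = solve_mean_within_degree(q, d_mean, sizes)
        assert 0 <= dw <= d_mean + 1e-12
        assert expected_modularity(dw, sizes, d_mean, 25 * k) == pytest.approx(
            q, abs=1e-12
        )

    def test_infeasible_target_names_the_range(self):
        with pytest.raises(FeasibilityError, match="admissible range"):
            solve_mean_within_degree(0.95, 10.0, [50] * 4)


class TestQMax:
    @pytest.mark.parametrize("k, expect", [(1, 0.0), (3, 2 / 3), (10, 0.9)])
    def test_closed_form(self, k, expect):
        assert q_max(k) == pytest.approx(expect, abs=1e-15)

    def test_strictly_increasing_to_one(self):
        vals = [q_max(k) for k in range(1, 200)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert q_max(10**9) == pytest.approx(1.0, abs=1e-8)

    def test_k_below_one_is_an_error(self):
        with pytest.raises(InputError):
            q_max(0)


class TestBlockDensities:
    def test_reference_values(self):
        bd = block_densities(10.0, 7.0, 200.0, 10)
        assert bd.p_in == pytest.approx(7 / 199)
        assert bd.p_out == pytest.approx(3 / 1800)

    def test_degenerate_directions(self):
        assert block_densities(10.0, 10.0, 50.0, 5).p_out == 0.0
        assert block_densities(10.0, 0.0, 50.0, 5).p_in == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            block_densities(10.0, 5.0, 1.0, 5)
        with pytest.raises(InputError):
            block_densities(10.0, 5.0, 50.0, 1)


# ---------------------------------------------------------------------------
# structural metrics vs independent implementations
# ---------------------------------------------------------------------------


def _igraph_of(graph):
    import igraph as ig

    return ig.Graph(n=graph.n_nodes, edges=list(graph.edges))


class TestStructuralMetrics:
    def test_star_and_path_are_perfectly_disassortative(self):
        star = SimpleGraph.from_edges(4, [(0, 1), (0, 2), (0, 3)])
        path = SimpleGraph.from_edges(3, [(0, 1), (1, 2)])
        assert degree_assortativity(star) == pytest.approx(-1.0)
        assert degree_assortativity(path) == pytest.approx(-1.0)

    def test_regular_graph_is_flagged_undefined(self):
        ring = SimpleGraph.from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        with pytest.warns(UserWarning, match="zero degree variance"):
            assert math.isnan(degree_assortativity(ring))

    def test_clustering_examples(self):
        tri = SimpleGraph.from_edges(3, [(0, 1), (0, 2), (1, 2)])
        star = SimpleGraph.from_edges(4, [(0, 1), (0, 2), (0, 3)])
        diag = SimpleGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert clustering_coefficient(tri) == pytest.approx(1.0)
        assert clustering_coefficient(star) == pytest.approx(0.0)
        # local coefficients: degree-2 nodes 1, degree-3 nodes 2/3
        assert clustering_coefficient(diag) == pytest.approx(5 / 6)
        assert clustering_coefficient(diag, method="transitivity") == pytest.approx(
            3 * 2 / (1 + 1 + 3 + 3), abs=1e-12
        )

    def test_path_length_examples(self):
        k4 = SimpleGraph.from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        p3 = SimpleGraph.from_edges(3, [(0, 1), (1, 2)])
        assert average_path_length(k4) == pytest.approx(1.0)
        assert average_path_length(p3) == pytest.approx(4 / 3)

    def test_disconnected_falls_back_to_largest_component(self):
        g = SimpleGraph.from_edges(5, [(0, 1), (1, 2), (3, 4)])
        with pytest.warns(UserWarning, match="largest connected component"):
            assert average_path_length(g) == pytest.approx(4 / 3)

    def test_metrics_agree_with_igraph_on_random_graphs(self, rng):
        ig = pytest.importorskip("igraph")
        checked = 0
        while checked < 20:
            n = int(rng.integers(6, 40))
            edges = random_simple_graph(n, 0.25, rng)
            if len(edges) < 3:
                continue
            g = SimpleGraph.from_edges(n, edges)
            h = _igraph_of(g)
            deg = g.degrees()
            if np.ptp(deg[np.array(sorted(g.edges)).ravel()]) > 0:
                r_ref = h.assortativity_degree(directed=False)
                if not math.isnan(r_ref):
                    assert degree_assortativity(g) == pytest.approx(r_ref, abs=1e-10)
            c_ref = h.transitivity_avglocal_undirected(mode="zero")
            assert clustering_coefficient(g) == pytest.approx(c_ref, abs=1e-10)
            if g.is_connected():
                assert average_path_length(g) == pytest.approx(
                    h.average_path_length(), abs=1e-10
                )
            checked += 1


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------


class TestPartitionComparison:
    def test_identical_partitions(self):
        p = Partition(np.array([1, 1, 2, 2, 3]))
        assert partition_jaccard(p, p) == pytest.approx(1.0)
        assert variation_of_information(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_four_node_example(self):
        # pairs: ab co-clustered in both (n11=1); cd only in p1 (n10=1);
        # ac, bc only in p2 (n01=2) -> J = 1/4
        p1 = Partition(np.array([1, 1, 2, 2]))
        p2 = Partition(np.array([1, 1, 1, 2]))
        assert partition_jaccard(p1, p2) == pytest.approx(1 / 4)

    def test_all_singletons_degenerate_case(self):
        p = Partition(np.arange(1, 5))
        with pytest.warns(UserWarning, match="undefined"):
            assert partition_jaccard(p, p) == 1.0

    def test_one_module_vs_singletons_vi_is_log_n(self):
        n = 7
        p1 = Partition.single(n)
        p2 = Partition(np.arange(1, n + 1))
        assert variation_of_information(p1, p2) == pytest.approx(math.log(n))
        assert variation_of_information(p1, p2, base=2) == pytest.approx(math.log2(n))

    def test_against_brute_force_and_igraph(self, rng):
        ig = pytest.importorskip("igraph")
        for _ in range(20):
            n = int(rng.integers(4, 12))
            a1 = rng.integers(1, 4, size=n)
            a2 = rng.integers(1, 4, size=n)
            a1[:3] = [1, 2, 3]
            a2[:3] = [1, 2, 3]
            p1, p2 = Partition(a1), Partition(a2)
            n11, n10, n01 = brute_pair_counts(a1, a2)
            if n11 + n10 + n01:
                assert partition_jaccard(p1, p2) == pytest.approx(
                    n11 / (n11 + n10 + n01)
                )
            vi = variation_of_information(p1, p2)
            assert vi == pytest.approx(brute_vi(a1, a2), abs=1e-10)
            vi_ig = ig.compare_communities(
                list(a1 - 1), list(a2 - 1), method="vi"
            )
            assert vi == pytest.approx(vi_ig, abs=1e-10)

    def test_vi_is_a_metric_on_small_partitions(self, rng):
        # symmetry, non-negativity, triangle inequality by random enumeration
        n = 6
        parts = [Partition(np.array(a)) for a in [
            [1, 1, 1, 1, 1, 1],
            [1, 1, 1, 2, 2, 2],
            [1, 2, 3, 1, 2, 3],
            [1, 1, 2, 2, 3, 3],
            [1, 2, 1, 2, 1, 2],
        ]]
        for pa in parts:
            for pb in parts:
                vab = variation_of_information(pa, pb)
                assert vab >= -1e-12
                assert vab == pytest.approx(
                    variation_of_information(pb, pa), abs=1e-12
                )
                for pc in parts:
                    assert vab <= (
                        variation_of_information(pa, pc)
                        + variation_of_information(pc, pb)
                        + 1e-9
                    )

    def test_node_set_mismatch_is_an_error(self):
        with pytest.raises(InputError):
            partition_jaccard(Partition.single(3), Partition.single(4))
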