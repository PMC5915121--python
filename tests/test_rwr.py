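import numpy as np
import pytest
import scipy.sparse as sp

from netprio import (
    IntegratedNetwork,
    SeedSet,
    build_transition,
    kernel_matrix,
    rwr_direct,
    rwr_iterative,
)

from conftest import network_from_edges, random_er_network


class TestBuildTransition:
    def test_column_stochastic_path_graph(self, path_abc):
        model = build_transition(path_abc, "column-stochastic", 0.5)
        W = model.W.toarray()
        b = path_abc.position("B")
        np.testing.assert_allclose(W[:, b], [0.5, 0.0, 0.5])
        np.testing.assert_allclose(W.sum(axis=0), [1, 1, 1])

    def test_symmetric_degree_triangle_is_half_adjacency(self, triangle):
        model = build_transition(triangle, "symmetric-degree", 0.5)
        np.testing.assert_allclose(model.W.toarray(),
                                   triangle.adjacency.toarray() / 2)

    def test_isolated_node_gets_zero_row_and_column(self):
        net = network_from_edges([("A", "B")], extra_nodes=["D"])
        model = build_transition(net, "column-stochastic", 0.3)
        d = net.position("D")
        W = model.W.toarray()
        assert not W[:, d].any() and not W[d, :].any()

    @pytest.mark.parametrize("r", [0.0, -0.2, 1.0001])
    def test_restart_probability_range_enforced(self, triangle, r):
        with pytest.raises(ValueError, match="restart"):
            build_transition(triangle, "column-stochastic", r)

    def test_empty_network_is_an_error(self):
        empty = IntegratedNetwork(node_index=[],
                                  adjacency=sp.csr_matrix((0, 0)))
        with pytest.raises(ValueError, match="empty"):
            build_transition(empty)

    def test_unknown_normalization_is_an_error(self, triangle):
        with pytest.raises(ValueError, match="normalization"):
            build_transition(triangle, "row-stochastic", 0.5)


class TestIterative:
    def test_restart_only_limit_returns_p0(self, triangle):
        model = build_transition(triangle, "column-stochastic", r=1.0)
        seeds = SeedSet.from_members(["a", "b"], triangle)
        out = rwr_iterative(model, seeds)
        np.testing.assert_array_equal(out.scores, seeds.restart_vector)
        assert out.converged

    def test_triangle_fixed_point(self, triangle):
        model = build_transition(triangle, "column-stochastic", r=0.5)
        seeds = SeedSet.from_members(["a"], triangle)
        out = rwr_iterative(model, seeds, tol=1e-14)
        np.testing.assert_allclose(out.scores, [0.6, 0.2, 0.2], atol=1e-12)

    def test_component_without_seeds_scores_exactly_zero(self):
        net = network_from_edges([("a", "b"), ("b", "c"), ("x", "y")])
        model = build_transition(net, "column-stochastic", 0.3)
        seeds = SeedSet.from_members(["a", "b"], net)
        out = rwr_iterative(model, seeds, tol=1e-14)
        assert out.scores[net.position("x")] == 0.0
        assert out.scores[net.position("y")] == 0.0

    def test_unnormalized_restart_vector_rejected(self, triangle):
        model = build_transition(triangle, "column-stochastic", 0.3)
        with pytest.raises(ValueError, match="sums to"):
            rwr_iterative(model, np.array([0.5, 0.0, 0.0]))

    def test_max_iter_exhaustion_reports_nonconvergence(self, triangle):
        model = build_transition(triangle, "column-stochastic", 0.1)
        seeds = SeedSet.from_members(["a"], triangle)
        out = rwr_iterative(model, seeds, tol=1e-15, max_iter=2)
        assert not out.converged and out.iterations_used == 2


class TestDirect:
    def test_single_isolated_node_retains_restart_share(self):
        # documented convention: a degree-0 node has an all-zero transition
        # column, so a lone restart node keeps exactly the r*p0 share
        net = IntegratedNetwork(node_index=["A"],
                                adjacency=sp.csr_matrix((1, 1)))
        model = build_transition(net, "column-stochastic", r=0.4)
        out = rwr_direct(model, np.array([1.0]))
        assert out.scores[0] == pytest.approx(0.4)

    def test_r_equal_one_returns_p0(self, triangle):
        model = build_transition(triangle, "column-stochastic", r=1.0)
        seeds = SeedSet.from_members(["b"], triangle)
        out = rwr_direct(model, seeds)
        np.testing.assert_allclose(out.scores, seeds.restart_vector,
                                   atol=1e-14)
        assert out.iterations_used == 0 and out.converged

    @pytest.mark.parametrize("normalization",
                             ["column-stochastic", "symmetric-degree"])
    def test_agrees_with_iterative_on_random_graphs(self, normalization):
        rng = np.random.default_rng(42)
        for _ in range(20):
            net = random_er_network(50, 0.08, rng)
            model = build_transition(net, normalization, r=0.3)
            seeds = SeedSet.from_members(
                list(rng.choice(net.node_index, 5, replace=False)), net)
            direct = rwr_direct(model, seeds)
            iterative = rwr_iterative(model, seeds, tol=1e-12, max_iter=5000)
            assert np.abs(direct.scores - iterative.scores).max() < 1e-8

    def test_node_cap_guard(self, triangle):
        model = build_transition(triangle, "column-stochastic", 0.3)
        seeds = SeedSet.from_members(["a"], triangle)
        with pytest.raises(ValueError, match="cap"):
            rwr_direct(model, seeds, node_cap=2)


class TestKernel:
    def test_kernel_times_p0_matches_direct_solve(self):
        rng = np.random.default_rng(7)
        net = random_er_network(40, 0.1, rng)
        model = build_transition(net, "column-stochastic", 0.3)
        K = kernel_matrix(model)
        p0 = rng.random(40)
        p0 /= p0.sum()
        direct = rwr_direct(model, p0)
        assert np.abs(K @ p0 - direct.scores).max() < 1e-10

    def test_symmetric_mode_gives_symmetric_kernel(self):
        rng = np.random.default_rng(8)
        net = random_er_network(30, 0.15, rng)
        model = build_transition(net, "symmetric-degree", 0.3)
        K = kernel_matrix(model)
        assert np.abs(K - K.T).max() <= 1e-10

    def test_triangle_kernel_column(self, triangle):
        model = build_transition(triangle, "column-stochastic", 0.5)
        K = kernel_matrix(model)
        np.testing.assert_allclose(K[:, triangle.position("a")],
                                   [0.6, 0.2, 0.2], atol=1e-12)

    def test_node_cap_error_advises_iterative(self, triangle):
        model = build_transition(triangle, "column-stochastic", 0.5)
        with pytest.raises(ValueError, match="rwr_iterative"):
            kernel_matrix(model, node_cap=2)


class TestProperties:
    def test_mass_conservation_column_stochastic(self):
        rng = np.random.default_rng(11)
        net = random_er_network(60, 0.1, rng)
        model = build_transition(net, "column-stochastic", 0.3)
        nonisolated = [net.node_index[i] for i in np.flatnonzero(net.degree)]
        seeds = SeedSet.from_members(nonisolated[:6], net)
        for out in (rwr_direct(model, seeds),
                    rwr_iterative(model, seeds, tol=1e-12)):
            assert abs(out.scores.sum() - 1.0) < 1e-8

    def test_restart_monotonicity(self, triangle):
        seeds = SeedSet.from_members(["a"], triangle)
        dist = {}
        for r in (0.1, 0.9, 1.0):
            model = build_transition(triangle, "column-stochastic", r)
            out = rwr_direct(model, seeds)
            dist[r] = np.abs(out.scores - seeds.restart_vector).sum()
        assert dist[1.0] == 0.0
        assert dist[0.9] < dist[0.1]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        edges = [("u1", "u2"), ("u2", "u3"), ("u3", "u4"), ("u1", "u4"),
                 ("u2", "u4")]
        relabel = {"u1": "z9", "u2": "m5", "u3": "a1", "u4": "k7"}
        net1 = network_from_edges(edges)
        net2 = network_from_edges([(relabel[a], relabel[b]) for a, b in edges])
        for net, seed_ids in ((net1, ["u2"]), (net2, [relabel["u2"]])):
            model = build_transition(net, "column-stochastic", 0.3)
            out = rwr_direct(model, SeedSet.from_members(seed_ids, net))
            if net is net1:
                ref = out.as_dict()
            else:
                got = out.as_dict()
        assert all(abs(ref[old] - got[new]) < 1e-12
                   for old, new in relabel.items())

    def test_linearity_in_restart_vector(self):
        rng = np.random.default_rng(17)
        net = random_er_network(30, 0.15, rng)
        model = build_transition(net, "column-stochastic", 0.3)
        a, b = net.node_index[3], net.node_index[20]
        both = rwr_direct(model, SeedSet.from_members([a, b], net)).scores
        single_a = rwr_direct(model, SeedSet.from_members([a], net)).scores
        single_b = rwr_direct(model, SeedSet.from_members([b], net)).scores
        assert np.abs(both - (single_a + single_b) / 2).max() < 1e-10

    def test_matches_networkx_personalized_pagerank(self):
        # independent oracle: personalized PageRank with alpha = 1 - r on an
        # undirected graph is the same fixed point as column-stochastic RWR
        import networkx as nx

        rng = np.random.default_rng(19)
        net = random_er_network(40, 0.12, rng)
        g = nx.Graph()
        g.add_nodes_from(net.node_index)
        for (a, b), w in net.edge_set().items():
            g.add_edge(a, b, weight=w)
        seeds = [net.node_index[i]
                 for i in np.flatnonzero(net.degree)[:4]]
        model = build_transition(net, "column-stochastic", 0.3)
        ours = rwr_direct(model, SeedSet.from_members(seeds, net)).as_dict()
        pr = nx.pagerank(g, alpha=0.7, personalization={s: 1.0 for s in seeds},
                         tol=1e-12, max_iter=1000, weight="weight")
        for nid in net.node_index:
            assert ours[nid] == pytest.approx(pr[nid], abs=1e-8)


class TestSeedSet:
    def test_restart_vector_sums_to_one(self, triangle):
        seeds = SeedSet.from_members(["a", "b", "c"], triangle)
        assert seeds.restart_vector.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_member_rejected(self, triangle):
        with pytest.raises(ValueError, match="not in network"):
            SeedSet.from_members(["a", "zz"], triangle)

    def test_empty_rejected(self, triangle):
        with pytest.raises(ValueError, match="non-empty"):
            SeedSet.from_members([], triangle)
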