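"""Graph metrics against closed forms and the brute-force oracle."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import _oracles as oracle
from conftest import net_from_adjacency, net_from_nx, random_connected_net
from covnet import (
    CovarianceSpec,
    build_covariance,
    characteristic_path_length,
    clustering_coefficient,
    correlation_matrix,
    generate_cohort,
    global_efficiency,
    identify_hubs,
    largest_component_relative_size,
    local_efficiency,
    modularity,
    modularity_q,
    node_betweenness,
    threshold_at_density,
)
from covnet.nulls import rewire_degree_preserving


class TestClosedForms:
    def test_complete_graph(self, complete4):
        assert clustering_coefficient(complete4) == 1.0
        assert characteristic_path_length(complete4) == 1.0
        assert global_efficiency(complete4) == 1.0
        assert local_efficiency(complete4) == 1.0
        assert modularity_q(complete4, np.zeros(4)) == pytest.approx(0.0)

    def test_star_graph(self, star5):
        assert clustering_coefficient(star5) == 0.0  # no triangles
        assert local_efficiency(star5) == 0.0  # edgeless neighbourhoods
        bc = node_betweenness(star5)
        assert bc[0] == pytest.approx(6.0)  # all C(4,2) leaf pairs
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_path_graph_lp(self, path4):
        # unordered pair distances: 1,2,3,1,2,1
        assert characteristic_path_length(path4) == pytest.approx(10 / 6)

    def test_path3_global_efficiency(self):
        net = net_from_nx(nx.path_graph(3))
        assert global_efficiency(net) == pytest.approx(5 / 6)

    def test_two_disjoint_edges_lp_one(self):
        net = net_from_adjacency(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]]
        )
        assert characteristic_path_length(net) == 1.0

    def test_empty_network(self):
        net = net_from_adjacency(np.zeros((5, 5)))
        assert global_efficiency(net) == 0.0
        assert clustering_coefficient(net) == 0.0
        with pytest.raises(ValueError):
            characteristic_path_length(net)

    def test_five_cycle_with_chord_clustering(self):
        g = nx.cycle_graph(5)
        g.add_edge(0, 2)
        net = net_from_nx(g)
        assert clustering_coefficient(net) == pytest.approx(
            oracle.clustering(net.adjacency)
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_random_small_graphs_match_brute_force(self, seed):
        net = random_connected_net(np.random.default_rng(seed))
        a = net.adjacency
        assert clustering_coefficient(net) == pytest.approx(
            oracle.clustering(a), abs=1e-10
        )
        assert characteristic_path_length(net) == pytest.approx(
            oracle.path_length(a), abs=1e-10
        )
        assert global_efficiency(net) == pytest.approx(
            oracle.global_eff(a), abs=1e-10
        )
        assert local_efficiency(net) == pytest.approx(
            oracle.local_eff(a), abs=1e-10
        )
        np.testing.assert_allclose(
            node_betweenness(net), oracle.betweenness(a), atol=1e-10
        )


class TestModularity:
    def test_two_triangles_component_partition(self, two_triangles):
        labels = [0, 0, 0, 1, 1, 1]
        assert modularity_q(two_triangles, labels) == pytest.approx(0.5)
        q, part = modularity(two_triangles, seed=0)
        assert q == pytest.approx(0.5)
        assert adjusted_rand_score(labels, part) == 1.0

    def test_no_edges_raises(self):
        net = net_from_adjacency(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            modularity(net, seed=0)

    def test_planted_modules_recovered(self):
        spec = CovarianceSpec(
            partition=tuple(i // 6 for i in range(24)),
            r_within=0.6,
            r_between=0.05,
        )
        cohort = generate_cohort(spec, spec, 200, 200, seed=5)
        net = threshold_at_density(correlation_matrix(cohort, "A"), 0.2)
        q, part = modularity(net, seed=1)
        assert adjusted_rand_score(spec.partition, part) >= 0.9

    def test_exceeds_rewired_null_modularity(self):
        spec = CovarianceSpec(
            partition=tuple(i // 6 for i in range(24)),
            r_within=0.6,
            r_between=0.05,
        )
        cohort = generate_cohort(spec, spec, 200, 200, seed=6)
        net = threshold_at_density(correlation_matrix(cohort, "A"), 0.2)
        q, _ = modularity(net, seed=2)
        null_qs = [
            modularity(rewire_degree_preserving(net, seed=s), seed=s)[0]
            for s in range(10)
        ]
        assert q > np.mean(null_qs)

    def test_determinism(self, two_triangles):
        r1 = modularity(two_triangles, seed=7, n_restarts=5)
        r2 = modularity(two_triangles, seed=7, n_restarts=5)
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[1], r2[1])


class TestHubs:
    def test_star_center_is_sole_hub(self, star5):
        table = identify_hubs(star5)
        assert table.iloc[0]["region"] == "n0"
        assert table.iloc[0]["normalized_betweenness"] == pytest.approx(5.0)
        assert table["is_hub"].sum() == 1
        # normalised betweenness averages to 1 by construction
        assert table["normalized_betweenness"].mean() == pytest.approx(1.0)

    def test_cycle_and_complete_have_no_hubs(self, cycle6, complete4):
        assert identify_hubs(cycle6)["is_hub"].sum() == 0
        with pytest.warns(UserWarning, match="no hubs"):
            table = identify_hubs(complete4)
        assert table["is_hub"].sum() == 0

    def test_sorted_descending(self, star5):
        nb = identify_hubs(star5)["normalized_betweenness"].to_numpy()
        assert np.all(np.diff(nb) <= 0)


class TestLargestComponent:
    def test_connected_is_one(self, cycle6):
        assert largest_component_relative_size(cycle6) == 1.0

    def test_empty_network_is_one_over_n(self):
        net = net_from_adjacency(np.zeros((68, 68)))
        assert largest_component_relative_size(net) == pytest.approx(1 / 68)

    def test_two_components(self):
        g = nx.disjoint_union(nx.complete_graph(40), nx.cycle_graph(28))
        assert largest_component_relative_size(net_from_nx(g)) == pytest.approx(
            40 / 68
        )


class TestEdgeMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_helps_efficiency_and_shortens_paths(self, seed):
        rng = np.random.default_rng(seed + 100)
        net = random_connected_net(rng, max_nodes=7)
        a = net.adjacency.copy()
        missing = [
            (i, j)
            for i in range(a.shape[0])
            for j in range(i + 1, a.shape[0])
            if not a[i, j]
        ]
        if not missing:
            return
        i, j = missing[rng.integers(len(missing))]
        a2 = a.copy()
        a2[i, j] = a2[j, i] = 1
        net2 = net_from_adjacency(a2)
        assert global_efficiency(net2) >= global_efficiency(net)
        assert characteristic_path_length(net2) <= characteristic_path_length(net)
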