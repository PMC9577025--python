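"""Network construction, topology metrics, hubs, consensus, overlap, export."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from zerolink import (
    AssociationNetwork,
    PairCorrelation,
    ProfileError,
    build_network,
    compute_metrics,
    consensus_network,
    export_network,
    hub_subnetwork,
    import_edge_tsv,
    overlap_counts,
)


def pc(i, j, r, p=1e-5, method="spearman", policy=1):
    return PairCorrelation(i, j, r=r, p=p, n_valid=50, method=method, policy=policy)


def net_from_edges(edges, kind="mixed"):
    g = nx.Graph()
    for u, v, r in edges:
        g.add_edge(u, v, sign="+" if r > 0 else "-", weight=float(r))
    return AssociationNetwork(g, kind)


class TestBuildNetwork:
    RESULTS = [pc("A", "B", 0.7), pc("A", "C", -0.65), pc("B", "C", 0.5)]

    def test_thresholding_by_sign(self):
        co = build_network(self.RESULTS, kind="co_occurrence")
        ex = build_network(self.RESULTS, kind="co_exclusive")
        assert co.edge_set() == {("A", "B", "+")}
        assert ex.edge_set() == {("A", "C", "-")}

    def test_nodes_are_endpoints_of_kept_edges(self):
        co = build_network(self.RESULTS, kind="co_occurrence")
        assert co.nodes == {"A", "B"}

    def test_boundaries_are_strict(self):
        at_r = [pc("A", "B", 0.6)]
        assert build_network(at_r, kind="co_occurrence").n_edges == 0
        at_p = [pc("A", "B", 0.9, p=0.001)]
        assert build_network(at_p, kind="co_occurrence").n_edges == 0

    def test_empty_input_gives_empty_network(self):
        net = build_network([], kind="co_occurrence")
        assert net.n_nodes == net.n_edges == 0

    def test_mixed_methods_rejected(self):
        bad = [pc("A", "B", 0.7), pc("A", "C", 0.8, method="pearson")]
        with pytest.raises(ProfileError):
            build_network(bad, kind="co_occurrence")

    def test_edge_count_monotone_in_cutoffs(self, rng):
        results = [
            pc(f"t{i}", f"t{j}", float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.01)))
            for i, j in itertools.combinations(range(12), 2)
        ]
        by_r = [build_network(results, r_cutoff=rc, kind="mixed").n_edges
                for rc in (0.2, 0.4, 0.6, 0.8)]
        assert by_r == sorted(by_r, reverse=True)
        by_p = [build_network(results, r_cutoff=0.3, p_cutoff=p, kind="mixed").n_edges
                for p in (0.01, 0.005, 0.001, 0.0001)]
        assert by_p == sorted(by_p, reverse=True)


class TestMetrics:
    def test_triangle(self):
        m = compute_metrics(net_from_edges([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)]))
        assert m.density == pytest.approx(1.0)
        assert m.clustering_coefficient == pytest.approx(1.0)
        assert m.diameter == 1
        assert m.n_components == 1

    def test_path_graph(self):
        m = compute_metrics(net_from_edges([("A", "B", 1), ("B", "C", 1)]))
        assert m.characteristic_path_length == pytest.approx(4 / 3)
        assert m.diameter == 2
        assert m.radius == 1

    def test_regular_graph_has_zero_heterogeneity(self):
        square = net_from_edges([("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "A", 1)])
        assert compute_metrics(square).heterogeneity == pytest.approx(0.0)

    def test_empty_and_single_edge_graphs_do_not_crash(self):
        empty = compute_metrics(net_from_edges([]))
        assert empty.n_nodes == 0 and empty.n_components == 0
        single = compute_metrics(net_from_edges([("A", "B", 1)]))
        assert single.n_edges == 1
        assert math.isnan(single.centralization)  # undefined for N = 2

    def test_matches_brute_force_oracle_on_small_graphs(self, rng):
        # library-independent oracle: adjacency powers for shortest paths
        for trial in range(12):
            n = int(rng.integers(3, 9))
            adj = np.zeros((n, n), dtype=int)
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.45:
                    adj[i, j] = adj[j, i] = 1
            edges = [(f"n{i}", f"n{j}", 1.0)
                     for i, j in itertools.combinations(range(n), 2) if adj[i, j]]
            if not edges:
                continue
            present = sorted({u for e in edges for u in e[:2]})
            idx = {u: k for k, u in enumerate(present)}
            m = compute_metrics(net_from_edges(edges))

            sub = np.zeros((len(present), len(present)), dtype=int)
            for u, v, _ in edges:
                sub[idx[u], idx[v]] = sub[idx[v], idx[u]] = 1
            N = len(present)
            deg = sub.sum(axis=1)
            assert m.n_nodes == N
            assert m.avg_neighbors == pytest.approx(deg.mean())
            assert m.density == pytest.approx(sub.sum() / (N * (N - 1)))
            assert m.heterogeneity == pytest.approx(
                math.sqrt(deg.var()) / deg.mean(), abs=1e-12)
            if N > 2:
                assert m.centralization == pytest.approx(
                    N / (N - 2) * (deg.max() / (N - 1) - sub.sum() / (N * (N - 1))),
                    abs=1e-12)

            # brute-force all-pairs shortest paths (Floyd-Warshall)
            dist = np.where(sub > 0, 1.0, np.inf)
            np.fill_diagonal(dist, 0.0)
            for k in range(N):
                for i in range(N):
                    for j in range(N):
                        dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
            finite = dist[(dist > 0) & np.isfinite(dist)]
            if finite.size:
                assert m.characteristic_path_length == pytest.approx(finite.mean())

            # local clustering oracle, nodes with degree < 2 contribute 0
            cc = []
            for i in range(N):
                nbrs = np.flatnonzero(sub[i])
                if len(nbrs) < 2:
                    cc.append(0.0)
                    continue
                links = sum(sub[a, b] for a, b in itertools.combinations(nbrs, 2))
                cc.append(2 * links / (len(nbrs) * (len(nbrs) - 1)))
            assert m.clustering_coefficient == pytest.approx(np.mean(cc), abs=1e-12)


class TestHubs:
    def test_star_with_one_hub_covers_everything(self):
        star = net_from_edges([("hub", f"leaf{i}", 1.0) for i in range(6)])
        sub = hub_subnetwork(star, top_k=1)
        assert sub.nodes == star.nodes
        assert sub.n_edges == star.n_edges

    def test_tie_broken_lexicographically_and_logged(self):
        two = net_from_edges(
            [("a1", "a2", 1), ("a2", "a3", 1), ("a1", "a3", 1),
             ("b1", "b2", 1), ("b2", "b3", 1), ("b1", "b3", 1)]
        )
        sub = hub_subnetwork(two, top_k=1)
        assert sub.nodes == {"a1", "a2", "a3"}
        assert "degree_tie" in sub.provenance

    def test_matches_closed_neighborhood_oracle(self, rng):
        g = nx.gnm_random_graph(12, 24, seed=5)
        g = nx.relabel_nodes(g, {i: f"t{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, "+", "sign")
        nx.set_edge_attributes(g, 0.9, "weight")
        net = AssociationNetwork(g, "mixed")
        for k in (1, 3, 5):
            sub = hub_subnetwork(net, top_k=k)
            ranked = sorted(g.nodes, key=lambda n: (-g.degree(n), n))[:k]
            expected = set(ranked)
            for h in ranked:
                expected |= set(g.neighbors(h))
            assert sub.nodes == expected

    def test_empty_network_rejected(self):
        with pytest.raises(ProfileError):
            hub_subnetwork(net_from_edges([]), top_k=2)


class TestConsensus:
    A = [("A", "B", 0.8), ("B", "C", 0.7), ("C", "D", 0.9)]
    B = [("A", "B", 0.9), ("C", "D", 0.7), ("D", "E", 0.8)]
    C = [("A", "B", 0.7), ("C", "D", 0.8), ("A", "C", 0.9)]

    def test_self_consensus_is_identity(self):
        net = net_from_edges(self.A)
        cons = consensus_network([net, net])
        assert cons.edge_set() == net.edge_set()

    def test_disjoint_networks_give_empty(self):
        cons = consensus_network(
            [net_from_edges([("A", "B", 0.9)]), net_from_edges([("C", "D", 0.9)])]
        )
        assert cons.n_edges == 0

    def test_three_way_intersection_matches_set_oracle(self):
        nets = [net_from_edges(e) for e in (self.A, self.B, self.C)]
        cons = consensus_network(nets)
        expected = set.intersection(*(n.edge_set() for n in nets))
        assert cons.edge_set() == expected
        assert cons.nodes == {u for e in expected for u in e[:2]}

    def test_weight_is_mean_of_members(self):
        nets = [net_from_edges(e) for e in (self.A, self.B, self.C)]
        cons = consensus_network(nets)
        assert cons.graph["A"]["B"]["weight"] == pytest.approx((0.8 + 0.9 + 0.7) / 3)

    def test_subset_order_invariance_associativity(self):
        nets = [net_from_edges(e) for e in (self.A, self.B, self.C)]
        cons = consensus_network(nets)
        for n in nets:
            assert cons.edge_set() <= n.edge_set()
        rev = consensus_network(nets[::-1])
        assert rev.edge_set() == cons.edge_set()
        nested = consensus_network([consensus_network(nets[:2]), nets[2]])
        assert nested.edge_set() == cons.edge_set()

    def test_sign_must_match_for_overlap(self):
        pos = net_from_edges([("A", "B", 0.9)])
        neg = net_from_edges([("A", "B", -0.9)])
        assert consensus_network([pos, neg]).n_edges == 0

    def test_mixed_kinds_rejected(self):
        a = net_from_edges([("A", "B", 0.9)], kind="co_occurrence")
        b = net_from_edges([("A", "B", -0.9)], kind="co_exclusive")
        with pytest.raises(ProfileError):
            consensus_network([a, b])
        with pytest.raises(ProfileError):
            overlap_counts(a, b)


class TestOverlap:
    def test_identical_networks(self):
        net = net_from_edges(TestConsensus.A)
        assert overlap_counts(net, net) == (net.n_edges, net.n_nodes)

    def test_disjoint_networks(self):
        a = net_from_edges([("A", "B", 0.9)])
        b = net_from_edges([("C", "D", 0.9)])
        assert overlap_counts(a, b) == (0, 0)

    def test_hand_built_partial_overlap(self):
        a = net_from_edges([("A", "B", 0.9), ("B", "C", 0.8), ("C", "D", 0.7)])
        b = net_from_edges([("A", "B", 0.8), ("B", "C", 0.9), ("X", "C", 0.7)])
        # shared edges: AB, BC; shared nodes: A, B, C
        assert overlap_counts(a, b) == (2, 3)


class TestExport:
    def test_edge_tsv_round_trip(self, tmp_path):
        net = net_from_edges([("A", "B", 0.9), ("B", "C", -0.7)])
        path = tmp_path / "net.tsv"
        export_network(net, path, "edge_tsv")
        back = import_edge_tsv(path)
        assert back.edge_set() == net.edge_set()
        for u, v, _ in net.edge_set():
            assert back.graph[u][v]["weight"] == net.graph[u][v]["weight"]

    def test_graphml_loadable(self, tmp_path):
        net = net_from_edges([("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7)])
        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_empty_graphml_is_valid(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_network(net_from_edges([]), path, "graphml")
        assert nx.read_graphml(path).number_of_nodes() == 0
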