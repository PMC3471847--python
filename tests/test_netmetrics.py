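from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import calfnet as cn


def random_weighted_graph(rng, n_max=8, connected=False):
    while True:
        n = int(rng.integers(3, n_max + 1))
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for a, b in combinations(range(n), 2):
            if rng.random() < 0.6:
                G.add_edge(a, b, weight=float(rng.uniform(0.05, 1.0)))
        if G.number_of_edges() == 0:
            continue
        if connected and not nx.is_connected(G):
            continue
        return G


def brute_force_betweenness(G, node):
    """Exhaustive shortest-path enumeration with 1/weight edge lengths."""
    nodes = list(G.nodes)
    total = 0.0
    for s, t in combinations((v for v in nodes if v != node), 2):
        best, paths = np.inf, []
        for k in range(len(nodes)):
            for mids in permutations([v for v in nodes if v not in (s, t)], k):
                path = (s, *mids, t)
                if all(G.has_edge(a, b) for a, b in zip(path, path[1:])):
                    length = sum(1.0 / G.edges[a, b]["weight"]
                                 for a, b in zip(path, path[1:]))
                    if length < best - 1e-12:
                        best, paths = length, [path]
                    elif abs(length - best) <= 1e-12:
                        paths.append(path)
        if paths and np.isfinite(best):
            total += sum(node in p[1:-1] for p in paths) / len(paths)
    return total


class TestBasicMetrics:
    def test_star_center(self):
        G = nx.star_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        assert cn.binary_degree(G, 0) == 3
        assert cn.strength(G, 0) == pytest.approx(3.0)
        assert cn.clustering_coefficient(G, 0) == 0.0

    def test_isolated_node(self):
        G = nx.Graph()
        G.add_nodes_from([0, 1])
        G.add_edge(0, 1, weight=0.5)
        G.add_node(2)
        assert cn.binary_degree(G, 2) == 0
        assert cn.strength(G, 2) == 0.0

    def test_strength_sums_weights(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=0.2)
        G.add_edge("a", "c", weight=0.3)
        assert cn.strength(G, "a") == pytest.approx(0.5)

    def test_unknown_node_rejected(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        for fn in (cn.binary_degree, cn.strength, cn.weighted_betweenness,
                   cn.clustering_coefficient):
            with pytest.raises(ValueError):
                fn(G, 99)

    def test_triangle_clustering(self):
        G = nx.complete_graph(3)
        nx.set_edge_attributes(G, 0.4, "weight")
        assert cn.clustering_coefficient(G, 0) == 1.0


class TestBetweenness:
    def test_path_center(self):
        G = nx.path_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        assert cn.weighted_betweenness(G, 1) == pytest.approx(1.0)

    def test_equal_triangle_zero(self):
        G = nx.complete_graph(3)
        nx.set_edge_attributes(G, 0.5, "weight")
        assert cn.weighted_betweenness(G, 0) == pytest.approx(0.0)

    def test_strong_indirect_route_wins(self):
        """1/0.9 + 1/0.9 < 1/0.1: the strong 2-step route beats the weak tie."""
        G = nx.Graph()
        G.add_edge("A", "B", weight=0.9)
        G.add_edge("B", "C", weight=0.9)
        G.add_edge("A", "C", weight=0.1)
        assert cn.weighted_betweenness(G, "B") == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            G = random_weighted_graph(rng, n_max=6)
            vals = cn.weighted_betweenness_all(G)
            for node in G.nodes:
                assert vals[node] == pytest.approx(
                    brute_force_betweenness(G, node), abs=1e-8)


class TestEigenvector:
    def test_complete_graph_uniform(self):
        G = nx.complete_graph(4)
        nx.set_edge_attributes(G, 0.7, "weight")
        ev = cn.eigenvector_centrality(G)
        assert np.ptp(list(ev.values())) < 1e-9

    def test_star_ratio(self):
        """Star K1,3 principal eigenvector: leaves at 1/sqrt(3) of the center."""
        G = nx.star_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        ev = cn.eigenvector_centrality(G)
        assert ev[1] / ev[0] == pytest.approx(1 / np.sqrt(3), abs=1e-9)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            G = random_weighted_graph(rng, n_max=8, connected=True)
            ev = cn.eigenvector_centrality(G)
            A = nx.to_numpy_array(G, nodelist=list(G.nodes), weight="weight")
            w, v = linalg.eigh(A)
            ref = np.abs(v[:, -1])
            got = np.array([ev[n] for n in G.nodes])
            assert np.allclose(got / got.max(), ref / ref.max(), atol=1e-8)

    def test_edgeless_network_rejected(self):
        G = nx.Graph()
        G.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            cn.eigenvector_centrality(G)


class TestNormalization:
    def test_star_center_degree_one(self):
        G = nx.star_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        raw = cn.compute_raw_metrics(G, 0)
        norm = cn.normalize_metrics(G, raw)
        assert norm["degree"] == pytest.approx(1.0)
        assert norm["eigenvector"] == pytest.approx(1.0)

    def test_path_center_betweenness_one(self):
        G = nx.path_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        raw = cn.compute_raw_metrics(G, 1)
        norm = cn.normalize_metrics(G, raw)
        assert norm["betweenness"] == pytest.approx(1.0)

    def test_all_normalized_in_unit_interval(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            G = random_weighted_graph(rng)
            cache = {}
            for node in G.nodes:
                norm = cn.normalize_metrics(
                    G, cn.compute_raw_metrics(G, node, cache), cache)
                for k, v in norm.items():
                    assert -1e-12 <= v <= 1 + 1e-12, (k, v)

    def test_max_eigenvector_is_exactly_one(self):
        rng = np.random.default_rng(8)
        G = random_weighted_graph(rng, connected=True)
        cache = {}
        vals = [cn.normalize_metrics(G, cn.compute_raw_metrics(G, n, cache),
                                     cache)["eigenvector"] for n in G.nodes]
        assert max(vals) == pytest.approx(1.0)

    def test_uniform_weight_scaling_invariance(self):
        """Scaling all weights by c>0 moves strength by c, nothing else."""
        rng = np.random.default_rng(13)
        G = random_weighted_graph(rng, connected=True)
        H = G.copy()
        for _, _, d in H.edges(data=True):
            d["weight"] *= 0.37
        for node in G.nodes:
            cg, ch = {}, {}
            a = cn.normalize_metrics(G, cn.compute_raw_metrics(G, node, cg), cg)
            b = cn.normalize_metrics(H, cn.compute_raw_metrics(H, node, ch), ch)
            assert b["strength"] == pytest.approx(0.37 * a["strength"])
            for k in ("degree", "betweenness", "eigenvector", "clustering"):
                assert b[k] == pytest.approx(a[k], abs=1e-8)


class TestStandardize:
    def test_simple_column(self):
        df = pd.DataFrame({"norm_degree": [1.0, 2.0, 3.0]})
        out = cn.standardize_cohort(df, ["norm_degree"])
        assert list(out["std_degree"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_and_rank_preserved(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"norm_strength": rng.uniform(0, 1, 30)})
        out = cn.standardize_cohort(df, ["norm_strength"])
        assert out["std_strength"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["std_strength"].std(ddof=1) == pytest.approx(1.0)
        assert (out["std_strength"].rank() == df["norm_strength"].rank()).all()

    def test_zero_variance_named(self):
        df = pd.DataFrame({"norm_clustering": [0.5, 0.5, 0.5]})
        with pytest.raises(ValueError, match="norm_clustering"):
            cn.standardize_cohort(df, ["norm_clustering"])


class TestMaternalExclusion:
    def test_no_mother_edge_unchanged(self):
        G = nx.path_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        val, removed = cn.eigenvector_excluding_mother(G, 0, 99)
        assert not removed
        cache = {}
        base = cn.normalize_metrics(G, cn.compute_raw_metrics(G, 0, cache), cache)
        assert val == pytest.approx(base["eigenvector"])

    def test_two_node_network_isolation_gives_zero(self):
        G = nx.Graph()
        G.add_edge("calf", "mom", weight=0.9)
        val, removed = cn.eigenvector_excluding_mother(G, "calf", "mom")
        assert removed and val == 0.0

    def test_removal_lowers_subject_centrality(self, small_dataset, small_subjects):
        surveys = cn.filter_unknown_ids(small_dataset.surveys)
        for sid in small_subjects.index:
            G = cn.build_infancy_network(sid, surveys, small_dataset.individuals)
            mother = small_dataset.individuals.loc[sid, "mother_id"]
            if G.has_edge(sid, mother):
                break
        else:
            pytest.fail("no subject with a maternal tie in the fixture cohort")
        cache = {}
        base = cn.normalize_metrics(G, cn.compute_raw_metrics(G, sid, cache),
                                    cache)["eigenvector"]
        val, removed = cn.eigenvector_excluding_mother(G, sid, mother)
        assert removed
        assert val <= base + 1e-9
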