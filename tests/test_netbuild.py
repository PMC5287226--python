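import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from shapegene import netbuild
from shapegene.config import PipelineConfig
from shapegene.netbuild import (
    PathSet,
    analyze,
    assemble_subnetwork,
    build_network,
    extract_paths,
    load_edges,
    stress_centrality,
)


# ----------------------------------------------------------------------
# brute-force oracle: enumerate every shortest path explicitly


def _bfs_dist(adj, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def _all_shortest_paths(adj, dist, s, t):
    if t not in dist:
        return []
    paths = []
    # restrict search to vertices on some s-t shortest path
    dist_t = _bfs_dist(adj, t)

    def walk2(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in adj[v]:
            if dist.get(w) == dist[v] + 1 and dist_t.get(w, 10 ** 9) == dist[t] - dist[w]:
                walk2(path + [w])

    walk2([s])
    return paths


def oracle_centralities(G):
    nodes = list(G)
    adj = {v: sorted(G.neighbors(v)) for v in nodes}
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}
    stress = {v: 0.0 for v in nodes}
    betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for v in nodes:
        dist = _bfs_dist(adj, v)
        reachable = len(dist) - 1
        total = sum(dist.values())
        closeness[v] = 0.0 if total == 0 else (reachable / total) * (reachable / (n - 1))
    for s, t in itertools.combinations(nodes, 2):
        dist = _bfs_dist(adj, s)
        paths = _all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                stress[v] += 1.0
                betweenness[v] += 1.0 / len(paths)
    return degree, closeness, stress, betweenness


# ----------------------------------------------------------------------
# load_edges


def _write_edges(tmp_path, rows, columns=("protein1", "protein2", "combined_score")):
    path = tmp_path / "edges.tsv"
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


def test_integer_dialect_normalized_and_boundary_kept(tmp_path):
    path = _write_edges(tmp_path, [("A", "B", 400), ("C", "D", 390)])
    edges = load_edges(path, 0.4)
    assert len(edges) == 1
    assert edges.iloc[0]["combined_score"] == pytest.approx(0.4)


def test_float_dialect_passthrough(tmp_path):
    path = _write_edges(tmp_path, [("A", "B", 0.95), ("C", "D", 0.39)])
    edges = load_edges(path, 0.4)
    assert len(edges) == 1
    assert edges.iloc[0]["combined_score"] == pytest.approx(0.95)


def test_reversed_duplicates_merged_keeping_max(tmp_path):
    path = _write_edges(tmp_path, [("A", "B", 500), ("B", "A", 700)])
    edges = load_edges(path, 0.4)
    assert len(edges) == 1
    assert edges.iloc[0]["combined_score"] == pytest.approx(0.7)


def test_self_loops_dropped(tmp_path):
    path = _write_edges(tmp_path, [("A", "A", 900), ("A", "B", 900)])
    edges = load_edges(path, 0.4)
    assert len(edges) == 1


def test_unknown_scale_rejected(tmp_path):
    path = _write_edges(tmp_path, [("A", "B", 1500)])
    with pytest.raises(ValueError, match="scale"):
        load_edges(path, 0.4)


# ----------------------------------------------------------------------
# build_network


def _sig(rows):
    return pd.DataFrame(rows, columns=["gene", "statistic", "rho", "p", "q"])


def test_minimal_network(cfg):
    sig = _sig([("G1", "cell_area|mean", 0.9, 1e-4, 1e-3)])
    edges = pd.DataFrame(columns=["node_a", "node_b", "combined_score"])
    G = build_network(sig, edges, cfg)
    assert G.number_of_nodes() == 2 + len(cfg.tf_list)
    assert G.number_of_edges() == 1
    assert G.nodes["G1"]["node_type"] == "gene"
    assert G.nodes["SMAD3"]["node_type"] == "tf"


def test_two_statistics_two_edges(cfg):
    sig = _sig([("G1", "cell_area|mean", 0.9, 1e-4, 1e-3),
                ("G1", "cell_area|sd", -0.8, 1e-3, 1e-2)])
    edges = pd.DataFrame(columns=["node_a", "node_b", "combined_score"])
    G = build_network(sig, edges, cfg)
    assert G.number_of_edges() == 2
    assert G.nodes["cell_area|mean"]["node_type"] == "feature"
    assert G.nodes["cell_area|sd"]["node_type"] == "feature"


def test_edge_count_recount(cfg, correlations, edge_table, network):
    _, sig = correlations
    retained = set(sig["gene"]) | set(cfg.tf_list)
    n_corr = len(sig.drop_duplicates(["gene", "statistic"]))
    n_inter = sum(
        1 for row in edge_table.itertuples(index=False)
        if row.node_a in retained and row.node_b in retained
    )
    assert network.number_of_edges() == n_corr + n_inter


def test_empty_correlations_rejected(cfg):
    with pytest.raises(ValueError):
        build_network(_sig([]), pd.DataFrame(), cfg)


# ----------------------------------------------------------------------
# centralities


def test_path_graph_hand_values():
    G = nx.path_graph(["A", "B", "C"])
    analyze(G)
    assert G.nodes["B"]["degree"] == 2
    assert G.nodes["B"]["stress"] == 1.0
    assert G.nodes["B"]["closeness"] == pytest.approx(1.0)
    assert G.nodes["B"]["betweenness"] == pytest.approx(1.0)
    for leaf in "AC":
        assert G.nodes[leaf]["stress"] == 0.0
        assert G.nodes[leaf]["betweenness"] == 0.0


def test_star_center_stress():
    G = nx.star_graph(4)  # center = 0, leaves 1..4
    stress = stress_centrality(G)
    assert stress[0] == 6.0  # C(4,2) leaf pairs
    assert all(stress[leaf] == 0.0 for leaf in range(1, 5))


@pytest.mark.parametrize("seed", range(10))
def test_centralities_match_oracle_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 16))
    G = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(0, 10 ** 6)))
    analyze(G)
    degree, closeness, stress, betweenness = oracle_centralities(G)
    for v in G.nodes:
        assert G.nodes[v]["degree"] == degree[v]
        assert G.nodes[v]["closeness"] == pytest.approx(closeness[v])
        assert G.nodes[v]["stress"] == pytest.approx(stress[v])
        assert G.nodes[v]["betweenness"] == pytest.approx(betweenness[v])


def test_leaves_have_zero_stress_betweenness(network):
    for v, d in network.nodes(data=True):
        if d["degree"] == 1:
            assert d["stress"] == 0.0
            assert d["betweenness"] == 0.0
        if d["degree"] > 0:
            assert 0 < d["closeness"] <= 1.0


# ----------------------------------------------------------------------
# path extraction


def _typed_graph(edges, features=(), tfs=()):
    G = nx.Graph()
    for f in features:
        G.add_node(f, node_type="feature")
    for t in tfs:
        G.add_node(t, node_type="tf")
    for a, b in edges:
        for v in (a, b):
            if v not in G:
                G.add_node(v, node_type="gene")
        G.add_edge(a, b, edge_type="interaction")
    return G


def test_optimal_and_suboptimal_paths(cfg):
    G = _typed_graph(
        [("F", "G1"), ("G1", "TF"), ("F", "G2"), ("G2", "G3"), ("G3", "TF")],
        features=["F"], tfs=["TF"])
    ps = extract_paths(G, "F", "TF", cfg)
    assert ps.optimal_length == 2
    assert ["F", "G1", "TF"] in ps.paths
    assert ["F", "G2", "G3", "TF"] in ps.paths
    assert len(ps.paths) == 2


def test_paths_through_other_tf_excluded(cfg):
    G = _typed_graph([("F", "OTHER"), ("OTHER", "TF")],
                     features=["F"], tfs=["TF", "OTHER"])
    # OTHER is a preselected TF, so the only route is banned
    cfg2 = cfg.replace(tf_list=("TF", "OTHER"))
    ps = extract_paths(G, "F", "TF", cfg2)
    assert len(ps) == 0
    assert ps.optimal_length is None


def test_paths_through_other_feature_excluded(cfg):
    G = _typed_graph([("F", "G1"), ("G1", "F2"), ("F2", "G2"), ("G2", "TF")],
                     features=["F", "F2"], tfs=["TF"])
    ps = extract_paths(G, "F", "TF", cfg)
    assert len(ps) == 0


def test_missing_endpoint_errors(cfg):
    G = _typed_graph([("F", "G1")], features=["F"], tfs=[])
    with pytest.raises(ValueError, match="TF"):
        extract_paths(G, "F", "TF", cfg)


def _oracle_simple_paths(G, s, t, max_len):
    paths = []

    def dfs(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        if len(path) > max_len:
            return
        for w in sorted(G.neighbors(v)):
            if w not in path:
                dfs(path + [w])

    dfs([s])
    return sorted(paths, key=lambda p: (len(p), p))


@pytest.mark.parametrize("seed", range(8))
def test_path_sets_match_exhaustive_dfs(cfg, seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(6, 14))
    base = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(0, 10 ** 6)))
    G = nx.relabel_nodes(base, {i: f"G{i}" for i in base.nodes})
    for v in G.nodes:
        G.nodes[v]["node_type"] = "gene"
    G.add_node("F", node_type="feature")
    G.add_node("TF", node_type="tf")
    for v in list(G.nodes)[:3]:
        if v not in ("F", "TF"):
            G.add_edge("F", v)
    for v in list(G.nodes)[3:6]:
        if v not in ("F", "TF"):
            G.add_edge("TF", v)
    ps = extract_paths(G, "F", "TF", cfg)
    if ps.optimal_length is None:
        assert not nx.has_path(G, "F", "TF")
        return
    expected = _oracle_simple_paths(G, "F", "TF",
                                    ps.optimal_length + cfg.path_slack)
    assert sorted(ps.paths) == sorted(expected)


def test_deleting_non_path_node_leaves_pathset_unchanged(cfg):
    G = _typed_graph([("F", "G1"), ("G1", "TF"), ("G9", "G8")],
                     features=["F"], tfs=["TF"])
    before = extract_paths(G, "F", "TF", cfg)
    G.remove_node("G9")
    after = extract_paths(G, "F", "TF", cfg)
    assert before.paths == after.paths


# ----------------------------------------------------------------------
# subnetwork assembly


def test_single_path_subnetwork(cfg):
    G = _typed_graph([("F", "G1"), ("G1", "TF")], features=["F"], tfs=["TF"])
    ps = extract_paths(G, "F", "TF", cfg)
    sub = assemble_subnetwork([ps], G)
    assert sub.number_of_nodes() == 3
    assert sub.number_of_edges() == 2


def test_chord_between_path_interiors_included(cfg):
    G = _typed_graph(
        [("F", "A"), ("A", "TF"), ("F", "B"), ("B", "TF"), ("A", "B")],
        features=["F"], tfs=["TF"])
    ps = extract_paths(G, "F", "TF", cfg)
    sub = assemble_subnetwork([ps], G)
    assert sub.has_edge("A", "B")  # chord, not on any single path


def test_subnetwork_contains_planted_regulators(study, subnetwork):
    planted = {g for (g, _tf) in study.truth.regulators}
    assert planted <= set(subnetwork.nodes)


def test_adding_edge_never_decreases_degree(network):
    degrees_before = dict(network.degree())
    H = network.copy()
    nodes = list(H.nodes)
    H.add_edge(nodes[0], nodes[-1])
    for v, d in degrees_before.items():
        assert H.degree(v) >= d
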