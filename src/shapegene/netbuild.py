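"""Shape-gene network assembly, centrality analysis, and path extraction.

Nodes are typed ``gene`` / ``tf`` / ``feature`` (feature statistics);
undirected edges are typed ``correlation`` (feature-gene) or ``interaction``
(gene-gene / gene-TF).  All path computations are unweighted hop counts —
interaction scores serve only as an inclusion filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "load_edges",
    "build_network",
    "analyze",
    "stress_centrality",
    "extract_paths",
    "assemble_subnetwork",
    "PathSet",
    "write_sif",
    "write_node_table",
]


# ----------------------------------------------------------------------
# edge loading


def load_edges(path: str | Path, min_score: float) -> pd.DataFrame:
    """Load an interaction edge table (STRING download dialect).

    The first two columns are node identifiers; a ``combined_score`` column
    holds either 0-1000 integers or 0-1 floats (detected from the data).
    Scores are normalized to [0, 1]; rows below ``min_score`` are dropped
    (``>=`` keeps the boundary); unordered duplicates are merged keeping the
    maximum score; self-loops are removed.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected two id columns plus scores")
    if "combined_score" not in df.columns:
        raise ValueError(f"{path}: no combined_score column")
    a_col, b_col = df.columns[:2]
    scores = df["combined_score"].astype(float)
    if (scores > 1000).any():
        raise ValueError(f"{path}: combined_score above 1000 — unknown score scale")
    if (scores > 1).any():
        scores = scores / 1000.0
    if (scores < 0).any():
        raise ValueError(f"{path}: negative combined_score")

    out = pd.DataFrame({
        "node_a": df[a_col].astype(str),
        "node_b": df[b_col].astype(str),
        "combined_score": scores,
    })
    out = out[out["node_a"] != out["node_b"]]
    out = out[out["combined_score"] >= min_score]
    key = out.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
    out = out.assign(_key=key)
    out = (
        out.sort_values("combined_score", ascending=False)
        .drop_duplicates("_key")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return out


# ----------------------------------------------------------------------
# network construction


def build_network(
    sig_corr: pd.DataFrame,
    edges: pd.DataFrame,
    config: PipelineConfig,
) -> nx.Graph:
    """Assemble the shape-gene network.

    Nodes: shape-correlated genes, the preselected TFs (retained even when
    isolated), and every feature statistic with at least one significant
    correlation.  Edges: one ``correlation`` edge per significant
    (gene, statistic) pair plus the ``interaction`` edges among retained
    genes/TFs.
    """
    if sig_corr.empty:
        raise ValueError("no significant correlations to build a network from")
    G = nx.Graph()
    tf_set = set(config.tf_list)
    genes = [g for g in dict.fromkeys(sig_corr["gene"]) if g not in tf_set]
    for g in genes:
        G.add_node(g, node_type="gene")
    for tf in config.tf_list:
        G.add_node(tf, node_type="tf")
    for stat in dict.fromkeys(sig_corr["statistic"]):
        G.add_node(stat, node_type="feature")

    for row in sig_corr.itertuples(index=False):
        G.add_edge(row.gene, row.statistic, edge_type="correlation", rho=float(row.rho))

    retained = set(genes) | tf_set
    for row in edges.itertuples(index=False):
        a, b = row.node_a, row.node_b
        if a in retained and b in retained and a != b:
            # correlation edges never collide: one endpoint is a feature node
            G.add_edge(a, b, edge_type="interaction",
                       combined_score=float(row.combined_score))
    return G


# ----------------------------------------------------------------------
# centralities


def _bfs_matrices(G: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and shortest-path counts (BFS per source)."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [[idx[w] for w in G.neighbors(v)] for v in nodes]
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for s in range(n):
        D[s, s] = 0
        S[s, s] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if D[s, w] == np.inf:
                        D[s, w] = d + 1
                        nxt.append(w)
                    if D[s, w] == d + 1:
                        S[s, w] += S[s, v]
            frontier = nxt
            d += 1
    return D, S


def stress_centrality(G: nx.Graph) -> dict:
    """Number of shortest paths through each node, once per unordered pair."""
    nodes = list(G.nodes)
    if not nodes:
        return {}
    D, S = _bfs_matrices(G, nodes)
    n = len(nodes)
    stress = {}
    for v in range(n):
        on_path = (D[:, v][:, None] + D[v, :][None, :]) == D
        counts = np.outer(S[:, v], S[v, :]) * on_path
        counts[v, :] = 0
        counts[:, v] = 0
        np.fill_diagonal(counts, 0)
        # unreachable pairs contribute 0 automatically (path counts are 0)
        stress[nodes[v]] = float(counts.sum()) / 2.0
    return stress


def analyze(G: nx.Graph) -> nx.Graph:
    """Attach degree, closeness, stress and betweenness to every node.

    Closeness is classical closeness within a node's component, scaled by
    (reachable / (n-1)); betweenness is unnormalized fractional shortest-path
    betweenness; stress counts whole shortest paths.
    """
    degree = dict(G.degree())
    closeness = nx.closeness_centrality(G)  # wf_improved component scaling
    betweenness = nx.betweenness_centrality(G, normalized=False)
    stress = stress_centrality(G)
    for v in G.nodes:
        G.nodes[v]["degree"] = int(degree[v])
        G.nodes[v]["closeness"] = float(closeness[v])
        G.nodes[v]["betweenness"] = float(betweenness[v])
        G.nodes[v]["stress"] = float(stress[v])
    return G


# ----------------------------------------------------------------------
# path extraction


@dataclass
class PathSet:
    """Simple paths from a feature statistic to a TF within the slack bound."""

    source: str
    target: str
    paths: list[list[str]] = field(default_factory=list)
    optimal_length: int | None = None
    slack: int = 0

    def __len__(self) -> int:
        return len(self.paths)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for p in self.paths:
            out.update(p)
        return out


def extract_paths(
    G: nx.Graph,
    feature_stat: str,
    tf: str,
    config: PipelineConfig,
) -> PathSet:
    """Optimal and suboptimal simple paths from a feature statistic to a TF.

    All other feature nodes and all other preselected TFs are deleted before
    the search, so no returned path routes through them.  Paths of length up
    to (shortest + ``config.path_slack``) hops are returned; an empty PathSet
    if the endpoints are disconnected.
    """
    for endpoint in (feature_stat, tf):
        if endpoint not in G:
            raise ValueError(f"endpoint {endpoint!r} not in network")
    banned = {
        v for v, data in G.nodes(data=True)
        if (data.get("node_type") == "feature" and v != feature_stat)
        or (data.get("node_type") == "tf" and v != tf)
    }
    H = G.subgraph([v for v in G.nodes if v not in banned])
    slack = config.path_slack
    if not nx.has_path(H, feature_stat, tf):
        return PathSet(source=feature_stat, target=tf, slack=slack)
    optimal = nx.shortest_path_length(H, feature_stat, tf)
    paths = [
        list(p)
        for p in nx.all_simple_paths(H, feature_stat, tf, cutoff=optimal + slack)
    ]
    paths.sort(key=lambda p: (len(p), p))
    return PathSet(source=feature_stat, target=tf, paths=paths,
                   optimal_length=optimal, slack=slack)


def assemble_subnetwork(pathsets: list[PathSet], G: nx.Graph) -> nx.Graph:
    """Induced subgraph on the union of all path nodes.

    Every parent-network edge among those nodes is kept, not only the edges
    traversed by the paths.
    """
    nodes: set[str] = set()
    for ps in pathsets:
        nodes |= ps.nodes()
    return induced_subgraph(G, nodes)


def induced_subgraph(G: nx.Graph, nodes: set[str]) -> nx.Graph:
    """Induced subgraph preserving the parent's node order.

    ``G.subgraph(...)`` iterates the filter set, so its order is
    hash-dependent; exports must be byte-stable across processes.
    """
    H = nx.Graph(**G.graph)
    H.add_nodes_from((v, G.nodes[v]) for v in G.nodes if v in nodes)
    H.add_edges_from(
        (a, b, d) for a, b, d in G.edges(data=True) if a in nodes and b in nodes
    )
    return H


# ----------------------------------------------------------------------
# exports


def write_sif(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for a, b, data in sorted(G.edges(data=True)):
            writer.writerow([a, data.get("edge_type", "interaction"), b])


def write_node_table(G: nx.Graph, path: str | Path) -> None:
    rows = []
    for v, data in G.nodes(data=True):
        rows.append({
            "node": v,
            "node_type": data.get("node_type", ""),
            "degree": data.get("degree", ""),
            "closeness": data.get("closeness", ""),
            "stress": data.get("stress", ""),
            "betweenness": data.get("betweenness", ""),
        })
    pd.DataFrame(rows).sort_values("node").to_csv(path, sep="\t", index=False)
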