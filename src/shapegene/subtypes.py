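"""Cell-line clustering on subnetwork genes and differential networks.

Lines are clustered (Euclidean distance, complete linkage, k = 2) on
z-scored subnetwork-gene expression; per-cluster mean profiles then define
differential genes and two cluster-specific networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .config import PipelineConfig
from .morphology import ExpressionMatrix
from .netbuild import induced_subgraph

__all__ = ["ClusterAssignment", "DifferentialNetwork", "cluster_lines",
           "differential_networks"]


@dataclass
class ClusterAssignment:
    """Two-way cell-line partition with its linkage tree."""

    labels: dict[str, int]            # line -> 1 or 2
    linkage_matrix: np.ndarray
    lines: list[str]                  # order matching the linkage leaves

    def members(self, cluster: int) -> list[str]:
        return [line for line, c in self.labels.items() if c == cluster]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths = merge heights)."""
        n = len(self.lines)
        Z = self.linkage_matrix

        def height(i: int) -> float:
            return 0.0 if i < n else float(Z[i - n, 2])

        def render(i: int) -> str:
            if i < n:
                return self.lines[i]
            left, right = int(Z[i - n, 0]), int(Z[i - n, 1])
            h = height(i)
            parts = [
                f"{render(c)}:{h - height(c):.6g}" for c in (left, right)
            ]
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


@dataclass
class DifferentialNetwork:
    """Per-cluster networks plus per-gene differential statistics."""

    stats: pd.DataFrame               # gene x [mean_z_1, mean_z_2, mean_raw_1, mean_raw_2, delta, differential]
    graphs: dict[int, nx.Graph] = field(default_factory=dict)


def _zscore_genes(profiles: pd.DataFrame) -> pd.DataFrame:
    """z per gene (row) across lines, sample SD; constant rows dropped."""
    sd = profiles.std(axis=1, ddof=1)
    keep = sd > 0
    centered = profiles.loc[keep].sub(profiles.loc[keep].mean(axis=1), axis=0)
    return centered.div(sd[keep], axis=0)


def cluster_lines(expr: ExpressionMatrix, genes: list[str]) -> ClusterAssignment:
    """Cluster cell lines on the given genes' z-scored profiles.

    Agglomerative clustering with Euclidean distance and complete linkage,
    tree cut at k = 2.  Cluster 1 is the cluster containing the
    lexicographically smallest line, so labels are order-invariant.
    """
    profiles = expr.collapse_probes()
    present = [g for g in genes if g in profiles.index]
    if len(present) < 2:
        raise ValueError("need at least 2 subnetwork genes with expression")
    lines = list(profiles.columns)
    if len(lines) < 4:
        raise ValueError("need at least 4 cell lines")
    z = _zscore_genes(profiles.loc[present])
    if z.empty:
        raise ValueError("all gene profiles are constant across lines")

    X = z.T.to_numpy()                # observations = lines
    dists = pdist(X, metric="euclidean")
    if np.all(dists == 0):
        raise ValueError("all line profiles identical; clustering is degenerate")
    Z = linkage(dists, method="complete")
    raw = fcluster(Z, t=2, criterion="maxclust")
    anchor = min(lines)
    anchor_label = raw[lines.index(anchor)]
    labels = {line: (1 if lab == anchor_label else 2) for line, lab in zip(lines, raw)}
    if len(set(labels.values())) != 2:
        raise ValueError("clustering produced a single cluster")
    return ClusterAssignment(labels=labels, linkage_matrix=Z, lines=lines)


def differential_networks(
    subnet: nx.Graph,
    expr: ExpressionMatrix,
    clusters: ClusterAssignment,
    config: PipelineConfig,
) -> DifferentialNetwork:
    """Differential genes and the two cluster-specific subnetworks.

    A gene is differential when its cluster-mean z profiles differ by more
    than ``dz_cutoff`` in absolute value.  Non-differential genes are kept in
    a cluster's network only when their within-cluster mean raw expression
    reaches ``expr_floor``.  Edges are the subnetwork edges among retained
    nodes.  Feature nodes are not part of the expression space and are
    excluded.
    """
    profiles = expr.collapse_probes()
    genes = [
        v for v, d in subnet.nodes(data=True)
        if d.get("node_type") != "feature" and v in profiles.index
    ]
    if not genes:
        raise ValueError("no subnetwork genes with expression profiles")
    raw = profiles.loc[genes]
    z = _zscore_genes(raw).reindex(index=genes).fillna(0.0)

    members = {c: clusters.members(c) for c in (1, 2)}
    mean_z = {c: z[members[c]].mean(axis=1) for c in (1, 2)}
    mean_raw = {c: raw[members[c]].mean(axis=1) for c in (1, 2)}
    delta = mean_z[1] - mean_z[2]
    differential = delta.abs() > config.dz_cutoff

    stats = pd.DataFrame({
        "mean_z_1": mean_z[1],
        "mean_z_2": mean_z[2],
        "mean_raw_1": mean_raw[1],
        "mean_raw_2": mean_raw[2],
        "delta": delta,
        "abs_delta": delta.abs(),
        "differential": differential,
    })

    graphs: dict[int, nx.Graph] = {}
    for c in (1, 2):
        retained = [
            g for g in genes
            if differential[g] or mean_raw[c][g] >= config.expr_floor
        ]
        H = induced_subgraph(subnet, set(retained))
        for g in retained:
            H.nodes[g]["mean_z"] = float(mean_z[c][g])
            H.nodes[g]["mean_raw"] = float(mean_raw[c][g])
            H.nodes[g]["differential"] = bool(differential[g])
            H.nodes[g]["abs_delta"] = float(abs(delta[g]))
        graphs[c] = H
    return DifferentialNetwork(stats=stats, graphs=graphs)
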