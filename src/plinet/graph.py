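"""Graph-theoretic characterization of thresholded brain networks.

All metrics operate on binary, undirected graphs (edge = connection retained
by the proportional threshold), with unweighted hop-count shortest paths:

* degree centrality        DC_i = k_i / (N - 1)
* betweenness centrality   BC_i = 2 / ((N-1)(N-2)) * sum_{h<j, h,j != i}
                                  g_hj(i) / g_hj
* clustering coefficient   CC_i = 2 t_i / (k_i (k_i - 1))
* local efficiency         Eloc_i = efficiency of the subgraph induced by
                                    i's neighbors
* global efficiency        Eglob = mean over ordered pairs of 1 / d_ij,
                                   with 1/inf = 0 for unreachable pairs

Nodes of degree < 2 take CC = 0 and Eloc = 0 (standard network-neuroscience
convention for degenerate neighborhoods). Computation is delegated to
networkx; the test-suite cross-checks every metric against independent
brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .containers import ValidationError


@dataclass
class BrainGraph:
    """Binary symmetric adjacency with named nodes."""

    adjacency: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        A = (A != 0)
        np.fill_diagonal(A, False)
        self.adjacency = A
        self.node_names = tuple(self.node_names)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency.astype(int))
        return nx.relabel_nodes(G, dict(enumerate(self.node_names)))


def binarize(C: ConnectivityMatrix) -> BrainGraph:
    """Edge wherever a retained (nonzero) weight remains after thresholding."""
    return BrainGraph(adjacency=C.values != 0, node_names=C.channel_names)


def degree_centrality(G: BrainGraph) -> np.ndarray:
    if G.n_nodes < 2:
        raise ValidationError("degree centrality needs at least 2 nodes")
    k = G.adjacency.sum(axis=1)
    return k / (G.n_nodes - 1)


def betweenness_centrality(G: BrainGraph) -> np.ndarray:
    if G.n_nodes < 3:
        raise ValidationError("betweenness centrality needs at least 3 nodes")
    bc = nx.betweenness_centrality(G.to_networkx(), normalized=True)
    return np.array([bc[name] for name in G.node_names])


def clustering_coefficient(G: BrainGraph) -> np.ndarray:
    cc = nx.clustering(G.to_networkx())
    return np.array([cc[name] for name in G.node_names])


def local_efficiency(G: BrainGraph) -> np.ndarray:
    """Per-node efficiency of the neighborhood subgraph (0 if < 2 neighbors)."""
    g = G.to_networkx()
    out = np.zeros(G.n_nodes)
    for i, name in enumerate(G.node_names):
        neigh = list(g.neighbors(name))
        if len(neigh) < 2:
            continue
        out[i] = nx.global_efficiency(g.subgraph(neigh))
    return out


def global_efficiency(G: BrainGraph) -> float:
    if G.n_nodes < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(G.to_networkx()))


def node_metric_table(G: BrainGraph, band: str = "", group: str = "",
                      subject_id: str = "") -> pd.DataFrame:
    """All node metrics for one graph as a tidy table (one row per node)."""
    df = pd.DataFrame({
        "channel": G.node_names,
        "degree_centrality": degree_centrality(G),
        "betweenness_centrality": betweenness_centrality(G),
        "clustering_coefficient": clustering_coefficient(G),
        "local_efficiency": local_efficiency(G),
    })
    df["global_efficiency"] = global_efficiency(G)
    if band:
        df.insert(0, "band", band)
    if group:
        df.insert(0, "group", group)
    if subject_id:
        df.insert(0, "subject_id", subject_id)
    return df
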