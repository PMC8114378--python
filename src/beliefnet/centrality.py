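"""Node centrality, weighted shortest paths, and sign-split subnetworks.

Centrality and path computations take absolute edge weights: an edge of
weight w becomes a link of length ``1/|w|``, so strong conditional
associations are short hops. Strength is the summed absolute weight of a
node's edges; closeness is the inverse of its total shortest-path
distance to the reachable nodes; betweenness counts (fractionally, for
ties) the shortest paths between other node pairs passing through the
node. The sign split partitions edges into a stimulating (positive) and
an inhibiting (negative) subnetwork, the latter stored with ``|w|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "strength",
    "to_distance",
    "shortest_paths_to",
    "closeness",
    "betweenness",
    "centrality_table",
    "split_by_sign",
    "PathResult",
]


@dataclass
class PathResult:
    """Shortest paths from every node to a focal node.

    ``distance[v]`` is the summed edge length of the shortest route from v
    to the focal node (0 for the focal node itself, ``inf`` if
    unreachable); ``path[v]`` is one shortest node sequence from v to the
    focal node (the lexicographically smallest among ties, empty when
    unreachable).
    """

    focal: str
    distance: dict[str, float]
    path: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": v,
                "distance": self.distance[v],
                "path": " -> ".join(self.path[v]),
            }
            for v in self.distance
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame["distance"] = [
            "-" if np.isinf(d) else f"{d:.6g}" for d in frame["distance"]
        ]
        frame.to_csv(Path(path), index=False)


def strength(net: WeightedNetwork) -> pd.Series:
    """s_i = sum_j |w_ij| (0 for isolated nodes)."""
    return pd.Series(
        np.abs(net.weights).sum(axis=1), index=net.node_labels, name="strength"
    )


def to_distance(net: WeightedNetwork, transform: str = "inverse") -> nx.Graph:
    """Distance graph: nonzero edges get length 1/|w| (or -log|w|).

    Absent edges get no entry at all — a missing association is not a
    zero-length link, so paths must route around it.
    """
    g = net.to_graph(distance=True)
    if transform == "inverse":
        return g
    if transform == "inverse_log":
        for u, v, data in g.edges(data=True):
            data["length"] = -np.log(abs(net.weights[net.index_of(u), net.index_of(v)]))
        return g
    raise ValueError(f"unknown distance transform {transform!r}")


def _lexmin_path(g: nx.Graph, dist: dict[str, float], source: str, focal: str) -> list[str]:
    """Lexicographically smallest shortest path source -> focal.

    Greedy over the shortest-path DAG: from each node pick the smallest
    neighbor label that stays on a shortest route to the focal node.
    """
    path = [source]
    node = source
    while node != focal:
        candidates = [
            v
            for v in g.neighbors(node)
            if abs(dist.get(v, np.inf) + g[node][v]["length"] - dist[node]) <= 1e-12
        ]
        node = min(candidates)
        path.append(node)
    return path


def shortest_paths_to(
    net: WeightedNetwork, focal: str, transform: str = "inverse"
) -> PathResult:
    """Dijkstra distances and one shortest path from every node to ``focal``.

    Ties are broken toward the lexicographically smallest node sequence
    so output is reproducible. Unreachable nodes get infinite distance
    and an empty path.
    """
    net.index_of(focal)  # raises KeyError for unknown labels
    g = to_distance(net, transform)
    dist = nx.single_source_dijkstra_path_length(g, focal, weight="length")
    distance: dict[str, float] = {}
    path: dict[str, list[str]] = {}
    for v in net.node_labels:
        if v in dist:
            distance[v] = float(dist[v])
            path[v] = _lexmin_path(g, dist, v, focal)
        else:
            distance[v] = np.inf
            path[v] = []
    return PathResult(focal=focal, distance=distance, path=path)


def closeness(net: WeightedNetwork, transform: str = "inverse", harmonic: bool = False) -> pd.Series:
    """c_i = 1 / sum_j d(i, j) over the nodes reachable from i.

    Nodes with no reachable partner get 0. With ``harmonic=True`` the sum
    of inverse distances is used instead, which is finite on disconnected
    graphs without per-component restriction.
    """
    g = to_distance(net, transform)
    if not nx.is_connected(g) and g.number_of_edges() > 0:
        logger.warning("network is disconnected; closeness computed per component")
    out = {}
    for v in net.node_labels:
        dist = nx.single_source_dijkstra_path_length(g, v, weight="length")
        others = [d for u, d in dist.items() if u != v]
        if not others:
            out[v] = 0.0
        elif harmonic:
            out[v] = float(sum(1.0 / d for d in others))
        else:
            out[v] = float(1.0 / sum(others))
    return pd.Series(out, name="closeness").reindex(net.node_labels)


def betweenness(net: WeightedNetwork, transform: str = "inverse") -> pd.Series:
    """Weighted betweenness with fractional credit for tied shortest paths.

    Endpoint pairs are excluded; counts are raw (unnormalized) pair
    counts, so a star center scores the number of leaf pairs.
    """
    g = to_distance(net, transform)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return pd.Series(bc, name="betweenness").reindex(net.node_labels)


def centrality_table(net: WeightedNetwork, transform: str = "inverse") -> pd.DataFrame:
    """Strength, closeness, and betweenness for every node."""
    return pd.concat(
        [strength(net), closeness(net, transform), betweenness(net, transform)], axis=1
    )


def split_by_sign(net: WeightedNetwork) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Partition edges by sign into stimulating and inhibiting subnetworks.

    The positive network keeps w > 0 edges unchanged; the negative
    network keeps w < 0 edges as |w|. Together they partition the
    original edge set.
    """
    w = net.weights
    pos = np.where(w > 0, w, 0.0)
    neg = np.where(w < 0, -w, 0.0)
    meta = {k: v for k, v in net.meta.items() if k != "n_edges"}
    return (
        WeightedNetwork(pos, net.node_labels, {**meta, "sign": "positive"}),
        WeightedNetwork(neg, net.node_labels, {**meta, "sign": "negative"}),
    )
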