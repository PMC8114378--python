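"""Network-level structure: communities, cliques, and signed cycles.

Communities are found by greedy agglomerative merging that maximizes
weighted modularity Q (on absolute weights), recording the full merge
history as a dendrogram. Cliques (complete subgraphs) and simple cycles
(rings) of a given size are enumerated separately — a four-cycle need
not be a clique — and every cycle is classified by the product of its
edge-weight signs: a positive product marks a reinforcing structure
(stimulation can circulate and accumulate), a negative product an
inhibiting one. Cross-sectional networks are undirected, so these loops
indicate potential, not demonstrated, feedback.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityPartition",
    "SignedCycleSet",
    "modularity",
    "greedy_communities",
    "within_cluster_strength",
    "enumerate_cliques",
    "enumerate_cycles",
    "classify_cycle",
]


@dataclass
class CommunityPartition:
    """Node -> community assignment with modularity and merge history.

    ``merge_history`` lists (community_a, community_b, modularity_after)
    tuples in merge order, community ids referring to the agglomeration
    state at the time of the merge — the dendrogram of the clustering.
    """

    assignment: dict[str, int]
    modularity: float
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return out


@dataclass
class SignedCycleSet:
    """Simple cycles with their edge-sign products and classification."""

    cycles: list[tuple[str, ...]]
    sign_product: list[int]
    classification: list[str]

    def __len__(self) -> int:
        return len(self.cycles)

    def to_json_lines(self, net: WeightedNetwork, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            for nodes, sp, cls in zip(self.cycles, self.sign_product, self.classification):
                idx = [net.index_of(v) for v in nodes]
                weights = [
                    float(net.weights[idx[i], idx[(i + 1) % len(idx)]])
                    for i in range(len(idx))
                ]
                fh.write(
                    json.dumps(
                        {"nodes": list(nodes), "weights": weights, "sign_product": sp, "class": cls}
                    )
                    + "\n"
                )


def modularity(net: WeightedNetwork, assignment: dict[str, int]) -> float:
    """Weighted modularity Q = sum_c (e_c/m - (a_c/m)^2) on |w|."""
    w = np.abs(net.weights)
    m = w.sum() / 2.0
    if m == 0:
        return 0.0
    labels = net.node_labels
    comm = np.array([assignment[v] for v in labels])
    q = 0.0
    for c in set(comm):
        mask = comm == c
        e_c = w[np.ix_(mask, mask)].sum() / 2.0
        a_c = w[mask].sum() / 2.0  # half the total strength of the community
        q += e_c / m - (a_c / m) ** 2
    return float(q)


def greedy_communities(net: WeightedNetwork) -> CommunityPartition:
    """Agglomerative merging maximizing weighted modularity.

    Starts from singleton communities and repeatedly merges the pair of
    communities with the largest modularity gain (smallest community-id
    pair among ties), recording every merge until one community remains;
    the returned assignment is the partition with maximal Q along the
    way. Negative weights enter as their absolute values, with a logged
    note.
    """
    w = np.abs(net.weights)
    if np.any(net.weights < 0):
        logger.info("negative weights present; community detection uses |w|")
    p = net.p
    labels = net.node_labels
    if net.n_edges == 0:
        return CommunityPartition({v: i for i, v in enumerate(labels)}, 0.0, [])

    m = w.sum() / 2.0
    # e[i][j]: fraction of total edge weight between communities i != j
    comms: dict[int, set[int]] = {i: {i} for i in range(p)}
    e: dict[int, dict[int, float]] = {
        i: {j: w[i, j] / (2 * m) for j in range(p) if j != i and w[i, j] > 0}
        for i in range(p)
    }
    a = {i: w[i].sum() / (2 * m) for i in range(p)}

    # modularity of the current partition, maintained incrementally
    q = sum(-a[i] ** 2 for i in comms)  # singletons: no internal weight
    best_q = q
    best_partition = {lab: i for i, lab in enumerate(labels)}
    history: list[tuple[int, int, float]] = []

    while len(comms) > 1:
        best_gain = -np.inf
        best_pair: tuple[int, int] | None = None
        for i in sorted(comms):
            for j in sorted(e[i]):
                if j <= i:
                    continue
                gain = 2 * (e[i][j] - a[i] * a[j])
                if gain > best_gain + 1e-15:
                    best_gain = gain
                    best_pair = (i, j)
        if best_pair is None:
            # disconnected remainder: merge the two smallest ids to
            # complete the dendrogram (gain from the a-term only)
            i, j = sorted(comms)[:2]
            best_gain = -2 * a[i] * a[j]
            best_pair = (i, j)
        i, j = best_pair
        comms[i] |= comms.pop(j)
        for k, v in e.pop(j).items():
            if k != i:
                e[i][k] = e[i].get(k, 0.0) + v
                e[k][i] = e[k].get(i, 0.0) + e[k].pop(j)
            else:
                e[i].pop(j, None)
        e[i].pop(j, None)
        a[i] = a[i] + a.pop(j)
        q += best_gain
        history.append((i, j, float(q)))
        if q > best_q + 1e-12:
            best_q = q
            best_partition = {}
            for cid, members in comms.items():
                for node_idx in members:
                    best_partition[labels[node_idx]] = cid
    # normalize community ids to 0..k-1 in order of first appearance
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for lab in labels:
        c = best_partition[lab]
        assignment[lab] = remap.setdefault(c, len(remap))
    q_check = modularity(net, assignment)
    return CommunityPartition(assignment, q_check, history)


def within_cluster_strength(
    net: WeightedNetwork, partition: CommunityPartition
) -> pd.Series:
    """Strength of each node on the subgraph induced by its own community."""
    if set(partition.assignment) != set(net.node_labels):
        raise ValueError("partition does not cover exactly the network's nodes")
    comm = np.array([partition.assignment[v] for v in net.node_labels])
    w = np.abs(net.weights)
    same = comm[:, None] == comm[None, :]
    return pd.Series(
        (w * same).sum(axis=1), index=net.node_labels, name="within_cluster_strength"
    )


def enumerate_cliques(net: WeightedNetwork, k: int) -> list[tuple[str, ...]]:
    """All k-cliques (complete subgraphs on k nodes), sorted canonically.

    Any nonzero weight counts as an edge.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    g = net.to_graph()
    out = [
        tuple(sorted(c)) for c in nx.enumerate_all_cliques(g) if len(c) == k
    ]
    return sorted(out)


def _canonical_cycle(nodes: tuple[str, ...]) -> tuple[str, ...]:
    """Smallest-label-first rotation, direction toward the smaller neighbor."""
    k = len(nodes)
    i = nodes.index(min(nodes))
    fwd = tuple(nodes[(i + s) % k] for s in range(k))
    rev = tuple(nodes[(i - s) % k] for s in range(k))
    return min(fwd, rev)


def enumerate_cycles(
    net: WeightedNetwork, length: int, chordless_only: bool = False
) -> SignedCycleSet:
    """All simple cycles of exactly ``length`` nodes, classified by sign.

    Each ring is reported once in canonical orientation. With
    ``chordless_only`` cycles whose node set carries extra edges are
    dropped. Lengths beyond 4 are allowed but cost grows combinatorially.
    """
    if length < 3:
        raise ValueError("cycle length must be >= 3")
    if length > 4:
        logger.warning("enumerating cycles of length %d may be slow", length)
    g = net.to_graph()
    seen: set[tuple[str, ...]] = set()
    cycles: list[tuple[str, ...]] = []
    for cyc in nx.simple_cycles(g, length_bound=length):
        if len(cyc) != length:
            continue
        canon = _canonical_cycle(tuple(cyc))
        if canon in seen:
            continue
        if chordless_only:
            sub = g.subgraph(canon)
            if sub.number_of_edges() > length:
                continue
        seen.add(canon)
        cycles.append(canon)
    cycles.sort()
    signs = []
    classes = []
    for cyc in cycles:
        cls = classify_cycle(net, list(cyc))
        signs.append(1 if cls == "reinforcing" else -1)
        classes.append(cls)
    return SignedCycleSet(cycles, signs, classes)


def classify_cycle(net: WeightedNetwork, cycle: list[str]) -> str:
    """Reinforcing iff the product of the cycle's edge signs is positive.

    Equivalently, a cycle is reinforcing iff it contains an even number
    of negative edges. Raises if a claimed edge is absent.
    """
    prod = 1.0
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        w = net.weights[net.index_of(a), net.index_of(b)]
        if w == 0.0:
            raise ValueError(f"cycle edge {a!r}-{b!r} is absent from the network")
        prod *= np.sign(w)
    return "reinforcing" if prod > 0 else "inhibiting"
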