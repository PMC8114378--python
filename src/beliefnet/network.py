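"""Signed weighted network container and serialization.

A :class:`WeightedNetwork` stores the symmetric matrix of partial
correlations over labeled nodes — the central object of every analysis.
Positive weights are stimulating associations, negative weights
inhibiting ones; magnitudes are conditional association strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

#: Entries below this magnitude are treated as exactly absent edges so that
#: graph algorithms operate on a true topology.
EDGE_EPS = 1e-8


@dataclass
class WeightedNetwork:
    """Symmetric signed edge-weight matrix over labeled nodes.

    Invariants: symmetric, zero diagonal, all ``|w| < 1``.
    ``meta`` records estimation parameters (selected lambda, gamma,
    correlation method, sparsity).
    """

    weights: np.ndarray
    node_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).copy()
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must match weights")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w[np.abs(w) < EDGE_EPS] = 0.0
        if np.any(np.abs(w) >= 1.0):
            raise ValueError("edge weights must satisfy |w| < 1")
        self.weights = w
        self.node_labels = [str(x) for x in self.node_labels]
        self.meta = dict(self.meta)
        self.meta.setdefault("n_edges", self.n_edges)

    # -- structure ---------------------------------------------------------

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.weights.shape[0], k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as (node_i, node_j, weight), i < j in label order."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.node_labels[i], self.node_labels[j], float(w)))
        return out

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"no such node: {label!r}") from None

    def to_graph(self, absolute: bool = False, distance: bool = False) -> nx.Graph:
        """NetworkX view; optionally |w| weights and 1/|w| edge lengths."""
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for u, v, w in self.edges():
            attrs = {"weight": abs(w) if absolute else w, "sign": 1 if w > 0 else -1}
            if distance:
                attrs["length"] = 1.0 / abs(w)
            g.add_edge(u, v, **attrs)
        return g

    # -- serialization -----------------------------------------------------

    def to_matrix_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=self.node_labels, columns=self.node_labels).to_csv(
            Path(path), float_format="%.17g"
        )

    def to_edgelist_csv(self, path: str | Path) -> None:
        rows = [
            {"node_i": u, "node_j": v, "weight": w} for u, v, w in self.edges()
        ]
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
            Path(path), index=False, float_format="%.17g"
        )

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), Path(path))

    @classmethod
    def from_matrix_csv(cls, path: str | Path) -> "WeightedNetwork":
        frame = pd.read_csv(Path(path), index_col=0)
        return cls(frame.to_numpy(dtype=float), list(frame.columns))

    @classmethod
    def from_edgelist_csv(
        cls, path: str | Path, node_labels: list[str] | None = None
    ) -> "WeightedNetwork":
        frame = pd.read_csv(Path(path))
        if node_labels is None:
            node_labels = sorted(
                set(frame["node_i"].astype(str)) | set(frame["node_j"].astype(str))
            )
        idx = {lab: i for i, lab in enumerate(node_labels)}
        w = np.zeros((len(node_labels), len(node_labels)))
        for _, row in frame.iterrows():
            i, j = idx[str(row["node_i"])], idx[str(row["node_j"])]
            w[i, j] = w[j, i] = row["weight"]
        return cls(w, node_labels)

    @classmethod
    def from_graphml(cls, path: str | Path) -> "WeightedNetwork":
        g = nx.read_graphml(Path(path))
        labels = list(g.nodes)
        idx = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        for u, v, data in g.edges(data=True):
            w[idx[u], idx[v]] = w[idx[v], idx[u]] = data["weight"]
        return cls(w, labels)
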