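"""Association network container and ordering-quality diagnostics.

The transcriptogram method starts from an undirected, unweighted
protein-protein association graph.  Genes whose products have no
association are excluded; every retained node therefore has degree >= 1.
Two diagnostics quantify how well a gene ordering groups associated
genes:

* the occupation fraction ``gamma(d)`` -- the fraction of a gene's
  association partners found at list distance ``d``, averaged over all
  genes; and
* the window modularity ``M_i(r)`` -- for the window of radius ``r``
  centred at position ``i``, the fraction of edges touching the window
  that lie entirely inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "GeneOrdering",
    "OccupationProfile",
    "ModularityProfile",
    "gamma_profile",
    "window_modularity",
]


class InteractionNetwork:
    """Undirected simple association graph with stable node order.

    Parameters
    ----------
    graph : networkx.Graph
        Simple undirected graph.  Self-loops are removed; isolated
        nodes are dropped (a gene with no association carries no
        ordering information).
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph(graph)
        g.remove_edges_from(nx.selfloop_edges(g))
        g.remove_nodes_from([n for n, d in g.degree() if d == 0])
        self._graph = g
        self.nodes: list = sorted(g.nodes(), key=str)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        # edge list in node-index space, u < v
        edges = []
        for u, v in g.edges():
            iu, iv = self._index[u], self._index[v]
            edges.append((iu, iv) if iu < iv else (iv, iu))
        edges.sort()
        self.edge_index = np.array(edges, dtype=np.int64).reshape(-1, 2)
        self.degrees = np.zeros(len(self.nodes), dtype=np.int64)
        for iu, iv in self.edge_index:
            self.degrees[iu] += 1
            self.degrees[iv] += 1
        # adjacency as list of neighbour index arrays
        self.neighbors = [
            np.fromiter((self._index[w] for w in g.neighbors(n)), dtype=np.int64)
            for n in self.nodes
        ]

    @classmethod
    def from_edges(cls, edges) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def index_of(self, node) -> int:
        return self._index[node]

    def __contains__(self, node) -> bool:
        return node in self._index

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class GeneOrdering:
    """A permutation of network nodes: position ``i`` holds ``order[i]``.

    Positions are 0-based internally; file formats use 1-based
    positions.  ``alpha`` and ``seed`` record how the ordering was
    produced (annealing provenance) and do not affect behaviour.
    """

    order: list
    alpha: float | None = None
    seed: int | None = None
    positions: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.order = list(self.order)
        self.positions = {g: i for i, g in enumerate(self.order)}
        if len(self.positions) != len(self.order):
            raise ValueError("ordering contains duplicate entries")

    @property
    def n(self) -> int:
        return len(self.order)

    def position_of(self, node) -> int:
        return self.positions[node]

    def relative_positions(self) -> np.ndarray:
        """Relative position (i - 1)/(N - 1) on the 1-based scale."""
        n = self.n
        if n == 1:
            return np.zeros(1)
        return np.arange(n) / (n - 1)

    def permutation_for(self, network: InteractionNetwork) -> np.ndarray:
        """pos[j] = list position of network node j; errors if any node missing."""
        missing = [n for n in network.nodes if n not in self.positions]
        if missing:
            raise ValueError(
                f"{len(missing)} network nodes missing from ordering "
                f"(first: {missing[0]!r})"
            )
        return np.fromiter(
            (self.positions[n] for n in network.nodes), dtype=np.int64
        )


@dataclass
class OccupationProfile:
    """gamma(d) for d = 1..N-1; sums to 1 over d."""

    gamma: np.ndarray  # index 0 <-> d = 1

    @property
    def distances(self) -> np.ndarray:
        return np.arange(1, len(self.gamma) + 1)

    def mass_within(self, d_max: int) -> float:
        """Total occupation fraction at distances d <= d_max."""
        return float(self.gamma[: d_max].sum())


@dataclass
class ModularityProfile:
    """M_i(r) per position; NaN where no edge touches the window."""

    values: np.ndarray
    radius: int

    @property
    def undefined(self) -> np.ndarray:
        return np.isnan(self.values)


def gamma_profile(network: InteractionNetwork, ordering: GeneOrdering) -> OccupationProfile:
    """Occupation fraction gamma(d), d = 1..N-1.

    For each gene the fraction of its k_i partners sitting at list
    distance d is accumulated, then averaged over genes, so each
    undirected edge contributes from both endpoints and
    sum_d gamma(d) == 1 exactly.
    """
    pos = ordering.permutation_for(network)
    n = ordering.n
    gamma = np.zeros(n - 1, dtype=float)
    if network.n_edges:
        iu = network.edge_index[:, 0]
        iv = network.edge_index[:, 1]
        d = np.abs(pos[iu] - pos[iv])  # in 1..n-1
        w = 1.0 / network.degrees[iu] + 1.0 / network.degrees[iv]
        np.add.at(gamma, d - 1, w)
    gamma /= network.n_nodes
    return OccupationProfile(gamma=gamma)


def window_modularity(
    network: InteractionNetwork, ordering: GeneOrdering, r: int
) -> ModularityProfile:
    """Window modularity M_i(r) = E_in / E_touch per list position.

    Windows truncate at the list ends (no wrap-around).  E_in counts
    edges with both endpoints inside the window, E_touch edges with at
    least one endpoint inside.  Positions whose window touches no edge
    are NaN (undefined), distinct from 0 (= all edges exit the window).
    """
    if r < 0:
        raise ValueError("radius must be >= 0")
    pos = ordering.permutation_for(network)
    n = ordering.n
    e_in = np.zeros(n + 1, dtype=np.int64)  # difference arrays
    e_touch = np.zeros(n + 1, dtype=np.int64)
    lo = np.minimum(pos[network.edge_index[:, 0]], pos[network.edge_index[:, 1]])
    hi = np.maximum(pos[network.edge_index[:, 0]], pos[network.edge_index[:, 1]])
    for a, b in zip(lo, hi):
        # centre positions whose window contains both endpoints
        start, stop = b - r, a + r
        if start <= stop:
            np.add.at(e_in, [max(0, start), min(n - 1, stop) + 1], [1, -1])
        # centre positions whose window contains >= 1 endpoint:
        # union of [a-r, a+r] and [b-r, b+r]
        if b - r <= a + r + 1:  # overlapping or adjacent -> one interval
            np.add.at(e_touch, [max(0, a - r), min(n - 1, b + r) + 1], [1, -1])
        else:
            np.add.at(e_touch, [max(0, a - r), min(n - 1, a + r) + 1], [1, -1])
            np.add.at(e_touch, [max(0, b - r), min(n - 1, b + r) + 1], [1, -1])
    e_in_c = np.cumsum(e_in[:-1]).astype(float)
    e_touch_c = np.cumsum(e_touch[:-1]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(e_touch_c > 0, e_in_c / e_touch_c, np.nan)
    return ModularityProfile(values=m, radius=r)
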