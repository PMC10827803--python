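"""Undirected interaction graphs on which agents learn.

Generation is delegated to networkx; graphs are stored in a compact CSR
(indptr/indices) adjacency form so the synchronous dynamics can evaluate all
neighbourhoods with vectorized array operations.  All generators return
simple undirected graphs and are deterministic in their seed.

Isolated nodes are possible (and kept) in sparse Erdős–Rényi graphs: such
agents never exploit and can only explore.  No connectivity repair is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "random_graph",
    "regular_random_graph",
    "small_world_graph",
    "complete_graph",
    "read_edge_list",
]


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph in CSR adjacency form.

    ``indices[indptr[i]:indptr[i+1]]`` are the (sorted) neighbours of node
    ``i``; every edge appears in both directions.
    """

    n_nodes: int
    indptr: np.ndarray
    indices: np.ndarray

    @classmethod
    def from_edges(cls, n_nodes: int, edges: np.ndarray | list) -> "Graph":
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= n_nodes):
            raise ValueError("edge endpoint out of range")
        if (edges[:, 0] == edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")
        # canonical undirected form, deduplicated
        und = np.sort(edges, axis=1)
        und = np.unique(und, axis=0) if und.size else und
        directed = np.concatenate([und, und[:, ::-1]]) if und.size else und
        order = np.lexsort((directed[:, 1], directed[:, 0])) if directed.size else []
        directed = directed[order] if len(order) else directed.reshape(0, 2)
        deg = np.bincount(directed[:, 0], minlength=n_nodes)
        indptr = np.concatenate([[0], np.cumsum(deg)]).astype(np.int64)
        return cls(int(n_nodes), indptr, directed[:, 1].copy())

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        edges = np.array([(u, v) for u, v in g.edges()], dtype=np.int64)
        return cls.from_edges(g.number_of_nodes(), edges.reshape(-1, 2))

    # -- queries -----------------------------------------------------------

    def neighbors(self, node: int) -> np.ndarray:
        return self.indices[self.indptr[node] : self.indptr[node + 1]]

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def n_edges(self) -> int:
        return int(self.indices.size // 2)

    @property
    def mean_degree(self) -> float:
        return float(self.indices.size / self.n_nodes)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array with u < v."""
        u = np.repeat(np.arange(self.n_nodes), self.degrees)
        mask = u < self.indices
        return np.column_stack([u[mask], self.indices[mask]])

    # -- i/o ---------------------------------------------------------------

    def write_edge_list(self, path: str | Path) -> None:
        """Two whitespace-separated 0-based node indices per line."""
        lines = [f"{u} {v}" for u, v in self.edges()]
        Path(path).write_text(f"# n_nodes {self.n_nodes}\n" + "\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> Graph:
    n_nodes = None
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[:1] == ["n_nodes"]:
                n_nodes = int(parts[1])
            continue
        u, v = line.split()
        edges.append((int(u), int(v)))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=-1)
    return Graph.from_edges(n_nodes, np.array(edges, dtype=np.int64).reshape(-1, 2))


def random_graph(n_nodes: int, mean_degree: float, seed: int) -> Graph:
    """Erdős–Rényi G(n, p) with p = mean_degree / (n_nodes - 1)."""
    if not 0 <= mean_degree <= n_nodes - 1:
        raise ValueError("mean_degree must lie in [0, n_nodes - 1]")
    p = mean_degree / (n_nodes - 1) if n_nodes > 1 else 0.0
    g = nx.gnp_random_graph(n_nodes, p, seed=int(seed))
    return Graph.from_networkx(g)


def regular_random_graph(n_nodes: int, degree: int, seed: int) -> Graph:
    """Random simple graph with every node of exactly ``degree``."""
    if degree >= n_nodes:
        raise ValueError("degree must be < n_nodes")
    if (n_nodes * degree) % 2 != 0:
        raise ValueError("n_nodes * degree must be even")
    g = nx.random_regular_graph(degree, n_nodes, seed=int(seed))
    return Graph.from_networkx(g)


def small_world_graph(
    n_nodes: int, degree: int, rewire_prob: float, seed: int
) -> Graph:
    """Watts–Strogatz ring lattice with independent edge rewiring."""
    if degree % 2 != 0:
        raise ValueError("degree must be even for the ring lattice")
    if degree >= n_nodes:
        raise ValueError("degree must be < n_nodes")
    if not 0 <= rewire_prob <= 1:
        raise ValueError("rewire_prob must lie in [0, 1]")
    g = nx.watts_strogatz_graph(n_nodes, degree, rewire_prob, seed=int(seed))
    return Graph.from_networkx(g)


def complete_graph(n_nodes: int) -> Graph:
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    return Graph.from_networkx(nx.complete_graph(n_nodes))
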