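"""Immutable simple undirected graph container.

All analysis in this package runs on simple (no self-loops, no multi-edges)
undirected graphs with contiguous 0-based integer node IDs.  The container
keeps a canonical edge array and lazily builds the CSR adjacency matrix that
the spectral and simulation code consume.  Original node labels from an edge
list file, when present, are preserved for reporting.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["Network"]


class Network:
    """A simple undirected graph on nodes ``0 .. N-1``.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``.  Isolated nodes are allowed.
    edges:
        Array-like of shape ``(E, 2)`` of distinct unordered pairs with
        ``u != v``.  Canonicalized internally to ``u < v``, sorted, deduplicated.
    labels:
        Optional sequence of original node labels, ``labels[i]`` being the
        label of internal node ``i``.
    """

    __slots__ = ("n_nodes", "edges", "labels", "_adj", "_degrees")

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        labels: Optional[Sequence] = None,
    ):
        n_nodes = int(n_nodes)
        if n_nodes < 1:
            raise ValueError("a network needs at least one node")
        arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                         dtype=np.int64)
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("edges must be pairs")
        if arr.size and (arr.min() < 0 or arr.max() >= n_nodes):
            raise ValueError("edge endpoint outside 0..N-1")
        if arr.size and np.any(arr[:, 0] == arr[:, 1]):
            raise ValueError("self-loops are not allowed")
        # canonical form: u < v, lexicographically sorted, unique
        lo = arr.min(axis=1)
        hi = arr.max(axis=1)
        canon = np.unique(np.column_stack([lo, hi]), axis=0)
        self.n_nodes = n_nodes
        self.edges = canon
        self.edges.setflags(write=False)
        if labels is not None and len(labels) != n_nodes:
            raise ValueError("labels length must equal n_nodes")
        self.labels = list(labels) if labels is not None else None
        self._adj = None
        self._degrees = None

    # -- basic views ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        if self._degrees is None:
            d = np.bincount(self.edges.ravel(), minlength=self.n_nodes)
            d.setflags(write=False)
            self._degrees = d
        return self._degrees

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix in CSR form."""
        if self._adj is None:
            u, v = self.edges[:, 0], self.edges[:, 1]
            row = np.concatenate([u, v])
            col = np.concatenate([v, u])
            data = np.ones(row.size, dtype=np.float64)
            self._adj = sp.csr_matrix(
                (data, (row, col)), shape=(self.n_nodes, self.n_nodes)
            )
        return self._adj

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]],
                   n_nodes: Optional[int] = None) -> "Network":
        """Build from raw integer pairs, dropping self-loops and duplicates."""
        arr = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
        arr = arr[arr[:, 0] != arr[:, 1]]
        if n_nodes is None:
            n_nodes = int(arr.max()) + 1 if arr.size else 1
        return cls(n_nodes, arr)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        nodes = list(g.nodes())
        index = {u: i for i, u in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.edges() if u != v]
        labels = None if nodes == list(range(len(nodes))) else nodes
        return cls(len(nodes), edges, labels=labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    # -- I/O -----------------------------------------------------------------

    def write_edge_list(self, path, header: Optional[str] = None) -> None:
        """Write as ``u v`` lines, 0-based IDs, '#'-prefixed comments."""
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            for u, v in self.edges:
                fh.write(f"{u} {v}\n")

    # -- dunder --------------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(N={self.n_nodes}, E={self.n_edges})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Network)
            and self.n_nodes == other.n_nodes
            and self.edges.shape == other.edges.shape
            and bool(np.all(self.edges == other.edges))
        )

    def __hash__(self):
        return hash((self.n_nodes, self.edges.tobytes()))
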