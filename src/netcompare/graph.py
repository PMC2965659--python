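"""Core graph data model.

A :class:`Graph` is a thin, validated wrapper around a dense adjacency
matrix.  Undirected graphs are stored symmetric; self-loops are forbidden;
unweighted graphs hold 0/1 entries.  The representation is deliberately
dense: the networks this package targets (sensor- or parcellation-level
connectivity) rarely exceed a few hundred nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

__all__ = ["Graph"]


@dataclass
class Graph:
    """A graph with ``N`` nodes given by its adjacency matrix.

    Parameters
    ----------
    adjacency : (N, N) array_like
        Edge indicators (unweighted) or nonnegative connection weights.
    directed : bool
        If False, the matrix must be symmetric.
    weighted : bool
        If False, entries must be 0 or 1.
    provenance : dict
        Free-form record of how the graph was produced (generator
        parameters, seed, thresholding report, warnings).
    """

    adjacency: np.ndarray
    directed: bool = False
    weighted: bool = False
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if a.shape[0] == 0:
            raise ValueError("empty graph (N=0) is not allowed")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(np.diagonal(a) != 0):
            raise ValueError("self-loops are forbidden (nonzero diagonal)")
        if not self.directed and not np.allclose(a, a.T):
            raise ValueError("undirected graph requires a symmetric adjacency matrix")
        if not self.weighted:
            vals = np.unique(a)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("unweighted graph entries must be 0 or 1")
            a = a.astype(np.int8)
        else:
            if np.any(a < 0):
                raise ValueError("weights must be nonnegative")
            a = a.astype(float)
        self.adjacency = a

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Edge count: undirected edges, or arcs for directed graphs."""
        nz = np.count_nonzero(self.adjacency)
        return nz if self.directed else nz // 2

    def degrees(self) -> np.ndarray:
        """Node degrees on the nonzero pattern (total degree if directed)."""
        pattern = self.adjacency != 0
        if self.directed:
            return pattern.sum(0) + pattern.sum(1)
        return pattern.sum(1)

    @property
    def average_degree(self) -> float:
        """k = 2E/N for undirected graphs (mean total degree if directed)."""
        return float(self.degrees().mean())

    @property
    def density(self) -> float:
        """Edge density E / (N(N-1)/2), arcs / N(N-1) for digraphs."""
        n = self.n_nodes
        possible = n * (n - 1) if self.directed else n * (n - 1) // 2
        return self.n_edges / possible

    # -- conversions ------------------------------------------------------

    def binary_pattern(self) -> "Graph":
        """Unweighted graph with the same nonzero pattern."""
        return Graph(
            (self.adjacency != 0).astype(np.int8),
            directed=self.directed,
            weighted=False,
            provenance=dict(self.provenance),
        )

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        cls = nx.DiGraph if self.directed else nx.Graph
        if self.weighted:
            return nx.from_numpy_array(self.adjacency, create_using=cls)
        g = cls()
        g.add_nodes_from(range(self.n_nodes))
        rows, cols = np.nonzero(self.adjacency)
        if self.directed:
            g.add_edges_from(zip(rows.tolist(), cols.tolist()))
        else:
            keep = rows < cols
            g.add_edges_from(zip(rows[keep].tolist(), cols[keep].tolist()))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph | nx.DiGraph, weighted: bool = False) -> "Graph":
        a = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
        return cls(a, directed=g.is_directed(), weighted=weighted)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Sorted (source, target, weight) triples; each undirected edge once."""
        rows, cols = np.nonzero(self.adjacency)
        out = []
        for i, j in zip(rows.tolist(), cols.tolist()):
            if not self.directed and i > j:
                continue
            out.append((i, j, float(self.adjacency[i, j])))
        return sorted(out)

    def copy(self) -> "Graph":
        return Graph(
            self.adjacency.copy(),
            directed=self.directed,
            weighted=self.weighted,
            provenance=dict(self.provenance),
        )
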