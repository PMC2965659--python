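"""Fundamental graph measures: degree statistics, path length, clustering,
synchronizability and central point dominance.

Conventions
-----------
* The characteristic path length ``L`` is the mean shortest-path hop count
  over *reachable* ordered node pairs; the fraction of reachable pairs is
  always reported alongside, and a strict policy that raises on
  disconnected graphs is available.
* Nodes of degree < 2 contribute a local clustering of 0 by default
  (configurable), which keeps ``C`` defined for every graph.
* Synchronizability is the Laplacian eigenratio ``lambda_max / lambda_2``;
  central point dominance (CPD) is Freeman's average gap between the
  maximum normalized betweenness and each node's betweenness.  Both are
  conventions: published work does not always agree on the exact formulas.
* On weighted graphs, ``L`` uses shortest paths over inverse weights and
  ``C`` the geometric-mean (Onnela) triangle convention; degree statistics
  use the nonzero pattern, flagged in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

from .graph import Graph

__all__ = [
    "MeasureSet",
    "degree_stats",
    "path_length",
    "clustering",
    "spectral_and_centrality",
    "measure_set",
]


@dataclass
class MeasureSet:
    """Named graph measures with provenance of how they were produced."""

    average_degree: float | None = None
    path_length: float | None = None
    clustering: float | None = None
    small_world_index: float | None = None
    n_hubs: int | None = None
    max_degree: int | None = None
    synchronizability: float | None = None
    central_point_dominance: float | None = None
    degree_distribution: dict[int, int] | None = None
    reachable_pair_fraction: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def as_records(self) -> list[dict[str, Any]]:
        """Tidy (measure, value) records for CSV export."""
        out = []
        for name in (
            "average_degree",
            "path_length",
            "clustering",
            "small_world_index",
            "n_hubs",
            "max_degree",
            "synchronizability",
            "central_point_dominance",
            "reachable_pair_fraction",
        ):
            v = getattr(self, name)
            if v is not None:
                out.append({"measure": name, "value": v, "provenance": repr(self.provenance)})
        return out


# ---------------------------------------------------------------------------
# degree statistics


def degree_stats(g: Graph, hub_rule: tuple[float, float] = (1.0, 2.0)) -> MeasureSet:
    """Average degree, degree distribution, maximum degree and hub count.

    ``hub_rule = (a, b)`` classifies a node as hub when its degree is
    *strictly* greater than ``a * mean_degree + b * sd_degree``.  The strict
    inequality makes regular graphs hub-free.  The rule is recorded in
    provenance.
    """
    prov: dict[str, Any] = {"hub_rule": hub_rule}
    if g.weighted:
        prov["degrees_on_nonzero_pattern"] = True
    deg = g.degrees()
    mean, sd = float(deg.mean()), float(deg.std())
    a, b = hub_rule
    n_hubs = int(np.sum(deg > a * mean + b * sd))
    dist: dict[int, int] = {}
    for d in deg.tolist():
        dist[int(d)] = dist.get(int(d), 0) + 1
    return MeasureSet(
        average_degree=mean,
        degree_distribution=dist,
        max_degree=int(deg.max()),
        n_hubs=n_hubs,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# path length


def _distance_matrix(g: Graph) -> np.ndarray:
    a = g.adjacency
    if g.weighted:
        # shortest paths over inverse weights: strong connections are short
        with np.errstate(divide="ignore"):
            lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
        return shortest_path(sp.csr_matrix(lengths), directed=g.directed)
    return shortest_path(sp.csr_matrix(a), directed=g.directed, unweighted=True)


def path_length(
    g: Graph, disconnected_policy: str = "connected_pairs_only"
) -> tuple[float, float]:
    """Characteristic path length ``L`` and the reachable-pair fraction.

    ``L`` is the mean shortest-path length over ordered reachable pairs.
    With ``disconnected_policy='error'`` a disconnected graph raises,
    naming the number of components.
    """
    if g.n_nodes < 2:
        raise ValueError("path length requires at least 2 nodes")
    if disconnected_policy not in ("connected_pairs_only", "error"):
        raise ValueError(f"unknown disconnected_policy {disconnected_policy!r}")
    d = _distance_matrix(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    reachable = np.isfinite(d) & off
    n_reach = int(reachable.sum())
    total = g.n_nodes * (g.n_nodes - 1)
    if n_reach == 0:
        raise ValueError("no reachable node pairs; path length undefined")
    frac = n_reach / total
    if frac < 1.0 and disconnected_policy == "error":
        n_comp, _ = connected_components(
            sp.csr_matrix(g.adjacency != 0), directed=g.directed, connection="strong"
        )
        raise ValueError(f"graph is disconnected ({n_comp} components)")
    return float(d[reachable].mean()), frac


# ---------------------------------------------------------------------------
# clustering


def clustering(g: Graph, low_degree: str = "zero") -> float:
    """Average clustering coefficient ``C``.

    Mean over nodes of (edges among neighbors) / (possible edges among
    neighbors).  ``low_degree='zero'`` lets nodes of degree < 2 contribute
    0; ``'exclude'`` drops them from the mean.
    """
    if g.n_nodes < 3:
        raise ValueError("clustering requires at least 3 nodes")
    if g.directed:
        raise ValueError("clustering is defined here for undirected graphs")
    if g.weighted:
        cc = nx.clustering(g.to_networkx(), weight="weight")
        local = np.array([cc[i] for i in range(g.n_nodes)])
        deg = g.degrees()
    else:
        a = g.adjacency.astype(np.float64)
        deg = a.sum(1)
        triangles = np.einsum("ij,jk,ki->i", a, a, a)  # 2x closed neighbor pairs
        denom = deg * (deg - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            local = np.where(denom > 0, triangles / denom, 0.0)
    if low_degree == "exclude":
        keep = deg >= 2
        if not np.any(keep):
            raise ValueError("no node has degree >= 2; clustering undefined")
        return float(local[keep].mean())
    if low_degree != "zero":
        raise ValueError(f"unknown low_degree policy {low_degree!r}")
    return float(local.mean())


# ---------------------------------------------------------------------------
# spectral / centrality measures


def spectral_and_centrality(g: Graph) -> MeasureSet:
    """Synchronizability (Laplacian eigenratio) and central point dominance."""
    if g.directed:
        raise ValueError("spectral measures are defined here for undirected graphs")
    a = (g.adjacency != 0).astype(float)
    lap = np.diag(a.sum(1)) - a
    eig = np.linalg.eigvalsh(lap)
    lam2, lam_max = eig[1], eig[-1]
    if lam2 < 1e-9:
        raise ValueError("graph is disconnected (lambda_2 = 0); synchronizability undefined")
    sync = float(lam_max / lam2)
    if g.n_nodes < 3:
        raise ValueError("central point dominance requires at least 3 nodes")
    bc = nx.betweenness_centrality(g.binary_pattern().to_networkx(), normalized=True)
    b = np.array([bc[i] for i in range(g.n_nodes)])
    cpd = float((b.max() - b).sum() / (g.n_nodes - 1))
    return MeasureSet(synchronizability=max(sync, 1.0), central_point_dominance=cpd)


# ---------------------------------------------------------------------------
# convenience


def measure_set(g: Graph, spectral: bool = True) -> MeasureSet:
    """All measures of a graph in one MeasureSet (SW excluded: it needs
    surrogates, see :mod:`netcompare.normalization`)."""
    ms = degree_stats(g)
    ms.path_length, ms.reachable_pair_fraction = path_length(g)
    if not g.directed:
        ms.clustering = clustering(g)
        if spectral and ms.reachable_pair_fraction == 1.0 and g.n_nodes >= 3:
            s = spectral_and_centrality(g)
            ms.synchronizability = s.synchronizability
            ms.central_point_dominance = s.central_point_dominance
    return ms
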