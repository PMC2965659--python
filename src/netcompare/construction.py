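"""Building graphs from connectivity matrices.

Empirical connectivity (coherence, phase uniformity, correlation, fiber
density, ...) arrives as a symmetric real matrix.  Three binarization
regimes are supported:

* ``fixed_threshold`` — keep pairs whose connectivity exceeds a threshold
  tau (strict inequality); the average degree then varies with overall
  connectivity level.
* ``fixed_degree`` — adjust the threshold per matrix so the average degree
  is fixed: keep the top round(N*k/2) pairs by connectivity.
* ``fixed_density`` — keep the top round(rho * N(N-1)/2) pairs.  For equal
  N this coincides with fixed_degree.

Ties at the cut value are broken by descending connectivity, then by
lexicographic node-pair order; the number of tied pairs at the cut is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import Graph

__all__ = ["ConnectivityMatrix", "BinarizationReport", "binarize", "weighted_graph"]

_SYM_TOL = 1e-9


@dataclass
class ConnectivityMatrix:
    """Symmetric real-valued connectivity before binarization."""

    values: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("connectivity matrix must be symmetric (tolerance 1e-9)")
        if self.node_labels is not None and len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length must match matrix size")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, value) arrays over the strict upper triangle."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        return iu, ju, self.values[iu, ju]


@dataclass
class BinarizationReport:
    mode: str
    threshold_used: float
    achieved_k: float
    achieved_density: float
    n_ties_broken: int


def _top_pairs(cm: ConnectivityMatrix, n_keep: int) -> tuple[Graph, float, int]:
    iu, ju, vals = cm.upper_pairs()
    if n_keep > len(vals):
        raise ValueError(f"target edge count {n_keep} exceeds the {len(vals)} available pairs")
    # sort by descending value, then lexicographic (i, j) for deterministic ties
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_keep]
    a = np.zeros((cm.n_nodes, cm.n_nodes), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    if n_keep == 0:
        return Graph(a), float("inf"), 0
    cut = vals[keep].min()
    n_at_cut = int(np.sum(vals == cut))
    n_kept_at_cut = int(np.sum(vals[keep] == cut))
    ties = n_at_cut - n_kept_at_cut  # pairs at the cut value that were dropped
    return Graph(a), float(cut), ties


def binarize(
    cm: ConnectivityMatrix, mode: str, value: float
) -> tuple[Graph, BinarizationReport]:
    """Convert a connectivity matrix into an unweighted graph.

    Parameters
    ----------
    cm : ConnectivityMatrix
    mode : {'fixed_threshold', 'fixed_degree', 'fixed_density'}
    value : tau for fixed_threshold, target average degree k for
        fixed_degree, or edge density rho in (0, 1) for fixed_density.
    """
    N = cm.n_nodes
    M = N * (N - 1) // 2
    if mode == "fixed_threshold":
        iu, ju, vals = cm.upper_pairs()
        keep = vals > value
        a = np.zeros((N, N), dtype=np.int8)
        a[iu[keep], ju[keep]] = 1
        a |= a.T
        g = Graph(a)
        thr, ties = float(value), 0
    elif mode == "fixed_degree":
        n_keep = int(round(N * value / 2.0))
        g, thr, ties = _top_pairs(cm, n_keep)
    elif mode == "fixed_density":
        if not 0.0 < value < 1.0:
            raise ValueError(f"edge density must lie in (0, 1), got {value}")
        n_keep = int(round(value * M))
        g, thr, ties = _top_pairs(cm, n_keep)
    else:
        raise ValueError(f"unknown binarization mode {mode!r}")
    report = BinarizationReport(
        mode=mode,
        threshold_used=thr,
        achieved_k=2.0 * g.n_edges / N,
        achieved_density=g.n_edges / M,
        n_ties_broken=ties,
    )
    g.provenance["binarization"] = report
    return g, report


def weighted_graph(cm: ConnectivityMatrix, significance_tau: float | None = None) -> Graph:
    """Weighted graph carrying the connectivity values as edge weights.

    Entries at or below ``significance_tau`` (when given) are zeroed; the
    diagonal is always zero.
    """
    v = cm.values.copy()
    if np.any(v < 0):
        raise ValueError("weights must be nonnegative connectivity strengths")
    np.fill_diagonal(v, 0.0)
    if significance_tau is not None:
        v[v <= significance_tau] = 0.0
    return Graph(v, weighted=True, provenance={"significance_tau": significance_tau})
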