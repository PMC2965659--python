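"""Direct graph-to-graph comparison: distances and correlations.

All measures here require the two graphs to have the same number of
nodes.  The Hamming distance counts disagreeing adjacency entries; the
structural distance minimizes it over node relabelings (exact for small
N, simulated annealing otherwise).  The graph correlation is the Pearson
correlation of the off-diagonal adjacency entries; because it is bounded
by the two graphs' edge counts, the attainable minimum/maximum are
reported and the correlation can be normalized by its attainable maximum.
Costa's coincidence similarity is the geometric mean of the fraction of
matched ones and matched zeros, both expressed relative to the first
graph's entries (it is asymmetric in its arguments by construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graph import Graph

__all__ = [
    "ComparisonResult",
    "hamming_distance",
    "structural_distance",
    "graph_correlation",
    "costa_similarity",
    "compare_all",
]

_EXACT_LIMIT = 8


@dataclass
class ComparisonResult:
    hamming: int | None = None
    structural: int | None = None
    structural_method: str | None = None
    covariance: float | None = None
    correlation: float | None = None
    correlation_bounds: tuple[float, float] | None = None
    normalized_correlation: float | None = None
    costa_similarity: float | None = None
    graph_means: tuple[float, float] | None = None


def _check_pair(g1: Graph, g2: Graph, unweighted: bool = True) -> None:
    if g1.n_nodes != g2.n_nodes:
        raise ValueError(
            "the adjacency matrices must match in size: "
            f"{g1.n_nodes} vs {g2.n_nodes} nodes"
        )
    if unweighted and (g1.weighted or g2.weighted):
        raise ValueError("this comparison requires unweighted graphs")
    if g1.directed != g2.directed:
        raise ValueError("cannot compare a directed with an undirected graph")


def _off_diag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def hamming_distance(g1: Graph, g2: Graph, pair_mode: str = "ordered") -> int:
    """Number of adjacency entries on which the two graphs disagree.

    In ``ordered`` mode the sum runs over all ordered pairs i != j, so an
    undirected edge difference counts twice; ``unordered`` halves this for
    undirected graphs.
    """
    _check_pair(g1, g2)
    off = _off_diag_mask(g1.n_nodes)
    d = int(np.sum((g1.adjacency != g2.adjacency) & off))
    if pair_mode == "ordered":
        return d
    if pair_mode == "unordered":
        if g1.directed:
            raise ValueError("unordered mode applies to undirected graphs")
        return d // 2
    raise ValueError(f"unknown pair_mode {pair_mode!r}")


def _permuted(a: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return a[np.ix_(perm, perm)]


def structural_distance(
    g1: Graph,
    g2: Graph,
    method: str = "exact",
    seed: int | None = None,
    n_proposals: int = 10_000,
) -> tuple[int, str]:
    """Minimum Hamming distance over node relabelings of the second graph.

    ``method='exact'`` enumerates all N! permutations (N <= 8 only);
    ``'anneal'`` runs seeded simulated annealing over transpositions with
    geometric cooling and returns the best value found, flagged
    approximate.  The annealed value never exceeds the plain Hamming
    distance.
    """
    _check_pair(g1, g2)
    n = g1.n_nodes
    a1, a2 = g1.adjacency, g2.adjacency
    off = _off_diag_mask(n)

    def dist(perm: np.ndarray) -> int:
        return int(np.sum((a1 != _permuted(a2, perm)) & off))

    if method == "exact":
        if n > _EXACT_LIMIT:
            raise ValueError(
                f"exact structural distance is limited to N <= {_EXACT_LIMIT} "
                f"(N={n}); use method='anneal'"
            )
        best = min(dist(np.array(p)) for p in itertools.permutations(range(n)))
        return best, "exact"
    if method != "anneal":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    perm = np.arange(n)
    cur = dist(perm)
    best = cur
    temp = max(1.0, n / 2.0)
    cooling = 0.999
    for _ in range(n_proposals):
        i, j = rng.choice(n, size=2, replace=False)
        cand = perm.copy()
        cand[i], cand[j] = cand[j], cand[i]
        d = dist(cand)
        if d <= cur or rng.random() < np.exp((cur - d) / temp):
            perm, cur = cand, d
            best = min(best, cur)
        temp *= cooling
    best = min(best, hamming_distance(g1, g2, "ordered"))
    return best, "anneal"


def graph_correlation(g1: Graph, g2: Graph) -> ComparisonResult:
    """Covariance and correlation of the off-diagonal adjacency entries.

    For unweighted graphs the entry means equal the edge densities, a
    correlation of 1 requires identical edge sets, and the attainable
    bounds given the two edge counts are reported together with the
    correlation normalized by its attainable maximum.
    """
    _check_pair(g1, g2, unweighted=False)
    n = g1.n_nodes
    off = _off_diag_mask(n)
    x = g1.adjacency[off].astype(float)
    y = g2.adjacency[off].astype(float)
    m1, m2 = float(x.mean()), float(y.mean())
    sx, sy = float(x.std()), float(y.std())
    if sx == 0.0:
        raise ValueError("first graph has zero variance (empty or complete)")
    if sy == 0.0:
        raise ValueError("second graph has zero variance (empty or complete)")
    cov = float(np.mean((x - m1) * (y - m2)))
    corr = cov / (sx * sy)
    bounds = None
    norm_corr = None
    if not (g1.weighted or g2.weighted):
        M = x.size  # ordered off-diagonal entries
        e1, e2 = int(x.sum()), int(y.sum())

        def corr_at_overlap(o: float) -> float:
            return (o * M - e1 * e2) / np.sqrt(e1 * (M - e1) * e2 * (M - e2))

        # correlation is increasing in the number of overlapping entries
        o_max = min(e1, e2)
        o_min = max(0, e1 + e2 - M)
        bounds = (float(corr_at_overlap(o_min)), float(corr_at_overlap(o_max)))
        if bounds[1] > 0:
            norm_corr = corr / bounds[1]
    return ComparisonResult(
        covariance=cov,
        correlation=corr,
        correlation_bounds=bounds,
        normalized_correlation=norm_corr,
        graph_means=(m1, m2),
    )


def costa_similarity(g1: Graph, g2: Graph) -> float:
    """Geometric mean of the matched-ones and matched-zeros ratios.

    r_ones = (# entries that are 1 in both) / (# ones in the first graph);
    r_zeros likewise for the off-diagonal zeros of the first graph.
    Returns 1 iff the adjacency matrices are identical, 0 for a
    complement pair.
    """
    _check_pair(g1, g2)
    off = _off_diag_mask(g1.n_nodes)
    a1 = g1.adjacency[off].astype(bool)
    a2 = g2.adjacency[off].astype(bool)
    n_ones = int(a1.sum())
    n_zeros = int((~a1).sum())
    if n_ones == 0 or n_zeros == 0:
        raise ValueError(
            "coincidence ratios undefined: first graph is empty or complete"
        )
    r_ones = np.sum(a1 & a2) / n_ones
    r_zeros = np.sum(~a1 & ~a2) / n_zeros
    return float(np.sqrt(r_ones * r_zeros))


def compare_all(
    g1: Graph, g2: Graph, seed: int | None = None, exact_limit: int = _EXACT_LIMIT
) -> ComparisonResult:
    """All pairwise comparison measures in one result."""
    res = graph_correlation(g1, g2)
    res.hamming = hamming_distance(g1, g2, "ordered")
    method = "exact" if g1.n_nodes <= exact_limit else "anneal"
    res.structural, res.structural_method = structural_distance(
        g1, g2, method=method, seed=seed
    )
    res.costa_similarity = costa_similarity(g1, g2)
    return res
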