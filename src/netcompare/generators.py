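"""Canonical network models and surrogate generators.

All stochastic generators take an integer seed and are bit-reproducible:
the same seed yields the identical graph.  Graphs carry their generator
parameters in ``provenance``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import networkx as nx
import numpy as np

from .graph import Graph

__all__ = [
    "GeneratorSpec",
    "ring_lattice",
    "erdos_renyi",
    "gnm_random",
    "watts_strogatz",
    "barabasi_albert",
    "rewire_preserving_degrees",
    "nearest_integer_lattice",
    "lattice_with_weights",
]


# ---------------------------------------------------------------------------
# deterministic lattices


def _lattice_offsets(N: int, k: int) -> list[int]:
    if k % 2 != 0:
        raise ValueError(f"ring lattice requires even k, got k={k}")
    if k < 2 or N < k + 1:
        raise ValueError(f"ring lattice requires N >= k+1 >= 3, got N={N}, k={k}")
    return list(range(1, k // 2 + 1))


def ring_lattice(N: int, k: int) -> Graph:
    """Ring lattice: each node linked to k/2 nearest neighbors on each side."""
    a = np.zeros((N, N), dtype=np.int8)
    for d in _lattice_offsets(N, k):
        idx = np.arange(N)
        a[idx, (idx + d) % N] = 1
        a[(idx + d) % N, idx] = 1
    return Graph(a, provenance={"generator": "ring_lattice", "N": N, "k": k})


def nearest_integer_lattice(N: int, E: int) -> Graph:
    """Ring-lattice-like graph with exactly E edges.

    Full neighbor rings are laid down for offsets 1..E//N; the remaining
    ``E mod N`` edges are placed at the next offset, round-robin from node
    0.  Used for fixed-density sweeps and as the lattice reference of
    range normalization, where 2E/N is not an even integer.
    """
    if E > N * (N - 1) // 2:
        raise ValueError(f"E={E} exceeds the {N * (N - 1) // 2} possible edges")
    a = np.zeros((N, N), dtype=np.int8)
    full, rem = divmod(E, N)
    if full > (N - 1) // 2:
        raise ValueError(f"E={E} too large for a lattice layout on N={N} nodes")
    idx = np.arange(N)
    for d in range(1, full + 1):
        a[idx, (idx + d) % N] = 1
        a[(idx + d) % N, idx] = 1
    d = full + 1
    for i in range(rem):
        a[i, (i + d) % N] = 1
        a[(i + d) % N, i] = 1
    return Graph(a, provenance={"generator": "nearest_integer_lattice", "N": N, "E": E})


# ---------------------------------------------------------------------------
# random models


def erdos_renyi(N: int, k: float, seed: int | None = None) -> Graph:
    """G(N, p) with edge probability p = k/(N-1); ensemble mean degree k."""
    if not 0 <= k <= N - 1:
        raise ValueError(f"require 0 <= k <= N-1, got k={k}, N={N}")
    rng = np.random.default_rng(seed)
    p = k / (N - 1)
    upper = np.triu(rng.random((N, N)) < p, 1)
    a = (upper | upper.T).astype(np.int8)
    return Graph(a, provenance={"generator": "erdos_renyi", "N": N, "k": k, "seed": seed})


def gnm_random(N: int, E: int, seed: int | None = None) -> Graph:
    """Uniform random graph with exactly N nodes and E edges."""
    M = N * (N - 1) // 2
    if not 0 <= E <= M:
        raise ValueError(f"require 0 <= E <= {M}, got E={E}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(M, size=E, replace=False)
    iu, ju = np.triu_indices(N, 1)
    a = np.zeros((N, N), dtype=np.int8)
    a[iu[chosen], ju[chosen]] = 1
    a |= a.T
    return Graph(a, provenance={"generator": "gnm_random", "N": N, "E": E, "seed": seed})


def watts_strogatz(N: int, k: int, p: float, seed: int | None = None) -> Graph:
    """Watts-Strogatz small-world graph.

    Starts from ``ring_lattice(N, k)``; each lattice edge is independently
    rewired with probability p by redrawing its far endpoint uniformly,
    avoiding self-loops and duplicates.  The number of rewired edges is
    recorded in ``provenance['n_rewired']`` and the surviving lattice
    ("local") edges can be identified via ``provenance['rewired_edges']``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must lie in [0, 1], got {p}")
    offsets = _lattice_offsets(N, k)
    if k >= N - 1:
        raise ValueError(f"rewiring impossible for near-complete lattice (N={N}, k={k})")
    rng = np.random.default_rng(seed)
    a = ring_lattice(N, k).adjacency.copy()
    rewired: list[tuple[int, int]] = []
    for d in offsets:
        for i in range(N):
            j = (i + d) % N
            if rng.random() >= p:
                continue
            # move the far endpoint of edge (i, j) to a fresh target
            for _ in range(100 * N):
                t = int(rng.integers(N))
                if t != i and a[i, t] == 0:
                    break
            else:  # pragma: no cover - guarded by the near-complete check
                raise RuntimeError("no free rewiring target found")
            a[i, j] = a[j, i] = 0
            a[i, t] = a[t, i] = 1
            rewired.append((min(i, t), max(i, t)))
    return Graph(
        a,
        provenance={
            "generator": "watts_strogatz",
            "N": N,
            "k": k,
            "p": p,
            "seed": seed,
            "n_rewired": len(rewired),
            "rewired_edges": rewired,
        },
    )


def barabasi_albert(N: int, m: int, seed: int | None = None) -> Graph:
    """Preferential-attachment scale-free graph with E = m(N-m) edges."""
    if not 1 <= m < N:
        raise ValueError(f"require N > m >= 1, got N={N}, m={m}")
    g = nx.barabasi_albert_graph(N, m, seed=seed)
    out = Graph.from_networkx(g)
    out.provenance = {"generator": "barabasi_albert", "N": N, "m": m, "seed": seed}
    return out


# ---------------------------------------------------------------------------
# degree-preserving surrogates (Maslov-Sneppen)


def rewire_preserving_degrees(
    g: Graph, n_swaps: int | None = None, seed: int | None = None
) -> Graph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Two edges (a, b) and (c, d) are replaced by (a, d) and (c, b); swaps
    creating self-loops or duplicate edges are rejected.  ``n_swaps``
    accepted swaps are performed (default ``10 * E``).  Works for
    undirected graphs (degree sequence preserved) and digraphs (in- and
    out-degree sequences preserved).  If no valid swap can be found the
    input is returned unchanged with a provenance warning.
    """
    if g.weighted:
        raise ValueError("degree-preserving rewiring requires an unweighted graph")
    edges = [(i, j) for i, j, _ in g.edge_list()]
    E = len(edges)
    if n_swaps is None:
        n_swaps = 10 * E
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    rng = np.random.default_rng(seed)
    a = g.adjacency.copy()
    prov = {
        "surrogate": "maslov_sneppen",
        "n_swaps_requested": n_swaps,
        "seed": seed,
    }
    if E < 2:
        prov["warning"] = "fewer than 2 edges; no swap possible"
        return Graph(a, directed=g.directed, weighted=False, provenance=prov)
    accepted = 0
    attempts = 0
    max_attempts = max(100 * n_swaps, 1000)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(E), rng.integers(E)
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        c1, d1 = edges[e2]
        if not g.directed and rng.random() < 0.5:
            c1, d1 = d1, c1  # undirected edges have no orientation
        if len({a1, b1, c1, d1}) < 4:
            continue
        if a[a1, d1] or a[c1, b1]:
            continue
        a[a1, b1] = a[c1, d1] = 0
        a[a1, d1] = a[c1, b1] = 1
        if not g.directed:
            a[b1, a1] = a[d1, c1] = 0
            a[d1, a1] = a[b1, c1] = 1
        edges[e1] = (a1, d1)
        edges[e2] = (c1, b1)
        accepted += 1
    prov["n_swaps_done"] = accepted
    if accepted == 0:
        prov["warning"] = "no valid double-edge swap exists; graph returned unchanged"
    elif accepted < n_swaps:
        prov["warning"] = f"only {accepted}/{n_swaps} swaps possible"
    return Graph(a, directed=g.directed, weighted=False, provenance=prov)


# ---------------------------------------------------------------------------
# weighted small-world construction from an empirical weight multiset


def lattice_with_weights(
    weights: Sequence[float], N: int, p: float, seed: int | None = None
) -> Graph:
    """Weighted small-world graph carrying an empirical weight multiset.

    The W weights are assigned uniformly at random to the edge slots of a
    nearest-integer ring lattice with W edges (so k is approximately
    2W/N); each edge is then rewired with probability p, Watts-Strogatz
    style, carrying its weight along.  The weight multiset is preserved
    exactly.
    """
    w = np.asarray(list(weights), dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    W = len(w)
    if W > N * (N - 1) // 2:
        raise ValueError(f"{W} weights exceed the {N * (N - 1) // 2} possible edges")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    slots = [(i, j) for i, j, _ in nearest_integer_lattice(N, W).edge_list()]
    order = rng.permutation(W)
    a = np.zeros((N, N), dtype=float)
    for slot_idx, w_idx in enumerate(order):
        i, j = slots[slot_idx]
        a[i, j] = a[j, i] = w[w_idx]
    n_rewired = 0
    for i, j in slots:
        if rng.random() >= p:
            continue
        for _ in range(100 * N):
            t = int(rng.integers(N))
            if t != i and a[i, t] == 0 and t != j:
                break
        else:
            continue  # no free target; leave the edge in place
        weight = a[i, j]
        a[i, j] = a[j, i] = 0.0
        a[i, t] = a[t, i] = weight
        n_rewired += 1
    return Graph(
        a,
        weighted=True,
        provenance={
            "generator": "lattice_with_weights",
            "N": N,
            "W": W,
            "p": p,
            "seed": seed,
            "n_rewired": n_rewired,
        },
    )


# ---------------------------------------------------------------------------
# declarative generator specification


@dataclass
class GeneratorSpec:
    """Serializable description of a network model draw."""

    topology: str  # lattice | erdos_renyi | watts_strogatz | barabasi_albert
    N: int
    k: float | None = None
    p: float | None = None
    m: int | None = None
    seed: int | None = None

    def sample(self, seed: int | None = None) -> Graph:
        s = self.seed if seed is None else seed
        if self.topology == "lattice":
            return ring_lattice(self.N, int(self.k))
        if self.topology == "erdos_renyi":
            return erdos_renyi(self.N, self.k, seed=s)
        if self.topology == "watts_strogatz":
            if self.p is None:
                raise ValueError("watts_strogatz requires rewiring probability p")
            return watts_strogatz(self.N, int(self.k), self.p, seed=s)
        if self.topology == "barabasi_albert":
            m = self.m if self.m is not None else max(1, int(round((self.k or 2) / 2)))
            return barabasi_albert(self.N, m, seed=s)
        raise ValueError(f"unknown topology {self.topology!r}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(**d)
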