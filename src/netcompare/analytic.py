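"""Closed-form approximations of L and C for canonical network topologies.

These are the standard large-N expressions for ring lattices,
Erdos-Renyi random graphs, Watts-Strogatz small-world networks and
Barabasi-Albert scale-free networks.  They exist to make N,k-dependence
explicit: L grows linearly in N and reciprocally in k for lattices,
logarithmically in N and k for Erdos-Renyi graphs, and double
logarithmically in N for scale-free networks, while C is N-free for
lattices but decays like k/N for random graphs.

The expressions are asymptotic; each topology's validity range is
enforced and out-of-range parameters raise with the violated condition.
The Watts-Strogatz path length uses the Newman-Moore-Watts crossover
form, accurate in the dilute-shortcut regime (p well below 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnalyticMeasures", "analytic_measures", "TOPOLOGIES"]

TOPOLOGIES = ("lattice", "erdos_renyi", "watts_strogatz", "barabasi_albert")


@dataclass(frozen=True)
class AnalyticMeasures:
    topology: str
    L_closed_form: float
    C_closed_form: float
    N: int
    k: float
    p: float | None = None


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"parameters outside validity range: {msg}")


def lattice_clustering(k: float) -> float:
    """C = 3(k-2) / (4(k-1)) for a ring lattice with k >= 2."""
    return 3.0 * (k - 2.0) / (4.0 * (k - 1.0))


def _nmw_f(u: float) -> float:
    # Newman-Moore-Watts scaling function; f(0) = 1/4 recovers the lattice
    if u <= 0:
        return 0.25
    return float(np.arctanh(np.sqrt(u / (u + 2.0))) / (2.0 * np.sqrt(u * u + 2.0 * u)))


def analytic_measures(
    topology: str, N: int, k: float, p: float | None = None
) -> AnalyticMeasures:
    """Closed-form L and C for the requested topology.

    Parameters
    ----------
    topology : {'lattice', 'erdos_renyi', 'watts_strogatz', 'barabasi_albert'}
    N, k : size and average degree; for Barabasi-Albert k = 2m.
    p : rewiring probability (Watts-Strogatz only).
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose from {TOPOLOGIES}")
    _require(N > 2, f"N > 2 required, got N={N}")
    if topology == "lattice":
        _require(k >= 2, f"lattice requires k >= 2, got k={k}")
        _require(N > 2 * k, f"lattice form requires N > 2k, got N={N}, k={k}")
        L = N / (2.0 * k)
        C = lattice_clustering(k)
        p_out = None
    elif topology == "erdos_renyi":
        _require(k > 1, f"Erdos-Renyi form requires k > 1, got k={k}")
        _require(k < N - 1, f"k < N-1 required, got k={k}, N={N}")
        L = float(np.log(N) / np.log(k))
        C = k / N
        p_out = None
    elif topology == "watts_strogatz":
        _require(p is not None, "Watts-Strogatz requires rewiring probability p")
        _require(0.0 <= p <= 1.0, f"p must lie in [0, 1], got p={p}")
        _require(k >= 2, f"requires k >= 2, got k={k}")
        _require(N > 2 * k, f"form requires N > 2k, got N={N}, k={k}")
        L = (2.0 * N / k) * _nmw_f(N * k * p / 2.0)
        C = lattice_clustering(k) * (1.0 - p) ** 3
        p_out = p
    else:  # barabasi_albert
        m = k / 2.0
        _require(m >= 1, f"Barabasi-Albert requires k = 2m >= 2, got k={k}")
        _require(N >= 16, f"double-logarithmic form requires N >= 16, got N={N}")
        L = float(np.log(N) / np.log(np.log(N)))
        C = (m / 8.0) * float(np.log(N)) ** 2 / N
        p_out = None
    return AnalyticMeasures(topology, float(L), float(C), N, float(k), p_out)
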