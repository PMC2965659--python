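"""Dyad and triad censuses for directed graphs, motif counting and
surrogate-based motif significance.

Directed three-node subgraphs fall into 16 isomorphism classes, labelled
by the conventional Davis-Leinhardt triad codes (003 ... 300); 13 of them
are weakly connected.  The classifier is built at import time by brute
force: each of the 64 labelled 3-node digraphs is reduced to a canonical
form by minimizing its 6-bit arc code over the 6 node permutations, and
canonical forms are named via fixed anchor representatives.

Motif significance compares observed motif counts with those of random
surrogates (Erdos-Renyi digraphs with matched average degree by default,
or degree-preserving rewirings), reporting z-scores and empirical
two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np

from .generators import rewire_preserving_degrees
from .graph import Graph

__all__ = [
    "TRIAD_LABELS",
    "CONNECTED_TRIAD_LABELS",
    "TriadCensus",
    "MotifSignificance",
    "dyad_census",
    "triad_census",
    "count_motif",
    "motif_significance",
    "directed_gnp",
    "functional_content",
    "triad_isomorphism_classes",
]

# Davis-Leinhardt order
TRIAD_LABELS = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

# arc code bit layout over nodes (a, b, c)
_PAIRS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))

# one labelled representative per class (arc code under the layout above)
_ANCHORS = {
    "003": 0, "012": 1, "102": 3, "021D": 5, "021U": 10, "021C": 6,
    "111D": 11, "111U": 7, "030T": 21, "030C": 25, "201": 15,
    "120D": 30, "120U": 23, "120C": 27, "210": 31, "300": 63,
}


def _permute_code(code: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for bit, (i, j) in enumerate(_PAIRS):
        if code >> bit & 1:
            out |= 1 << _PAIRS.index((perm[i], perm[j]))
    return out


def _build_lookup() -> tuple[np.ndarray, dict[str, int]]:
    perms = list(permutations(range(3)))
    canon = np.array([min(_permute_code(c, p) for p in perms) for c in range(64)])
    label_index = {lab: i for i, lab in enumerate(TRIAD_LABELS)}
    canon_to_class = {}
    for lab, anchor in _ANCHORS.items():
        canon_to_class[int(canon[anchor])] = label_index[lab]
    lookup = np.array([canon_to_class[int(c)] for c in canon], dtype=np.int64)
    return lookup, label_index


_TRIAD_LOOKUP, _LABEL_INDEX = _build_lookup()

CONNECTED_TRIAD_LABELS = tuple(l for l in TRIAD_LABELS if l not in ("003", "012", "102"))


def triad_isomorphism_classes() -> tuple[int, int]:
    """(number of directed-triad isomorphism classes, weakly connected ones),
    found by brute force over all 64 labelled 3-node digraphs."""
    perms = list(permutations(range(3)))
    classes: dict[int, int] = {}
    for code in range(64):
        classes.setdefault(min(_permute_code(code, p) for p in perms), code)
    n_connected = 0
    for rep in classes.values():
        und = np.zeros((3, 3), dtype=bool)
        for bit, (i, j) in enumerate(_PAIRS):
            if rep >> bit & 1:
                und[i, j] = und[j, i] = True
        # weakly connected iff no isolated node and the three nodes hang together
        deg = und.sum(1)
        if np.all(deg > 0):
            n_connected += 1
    return len(classes), n_connected


@dataclass
class TriadCensus:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(TRIAD_LABELS) - set(self.counts)
        if missing:
            raise ValueError(f"census missing labels: {sorted(missing)}")

    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[l] for l in TRIAD_LABELS])


def _require_directed(g: Graph) -> None:
    if not g.directed:
        raise ValueError("this census is defined for directed graphs")
    if g.weighted:
        raise ValueError("this census requires an unweighted graph")


def dyad_census(g: Graph) -> tuple[int, int, int]:
    """(mutual, asymmetric, null) dyad counts of a digraph."""
    _require_directed(g)
    a = g.adjacency.astype(bool)
    iu, ju = np.triu_indices(g.n_nodes, 1)
    fwd, bwd = a[iu, ju], a[ju, iu]
    mutual = int(np.sum(fwd & bwd))
    asym = int(np.sum(fwd ^ bwd))
    null = int(np.sum(~fwd & ~bwd))
    return mutual, asym, null


def _triple_codes(a: np.ndarray, i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
    return (
        a[i, j]
        | a[j, i] << 1
        | a[i, k] << 2
        | a[k, i] << 3
        | a[j, k] << 4
        | a[k, j] << 5
    )


def triad_census(g: Graph) -> TriadCensus:
    """Exact isomorphism-class counts of all C(N, 3) node triples."""
    _require_directed(g)
    n = g.n_nodes
    if n < 3:
        raise ValueError("triad census requires N >= 3")
    a = g.adjacency.astype(np.int64)
    triples = np.array(list(combinations(range(n), 3)))
    codes = _triple_codes(a, triples[:, 0], triples[:, 1], triples[:, 2])
    counts = np.bincount(_TRIAD_LOOKUP[codes], minlength=16)
    return TriadCensus({lab: int(counts[i]) for i, lab in enumerate(TRIAD_LABELS)})


# ---------------------------------------------------------------------------
# motif counting (shared with the ERGM statistics)


def count_motif(g: Graph, label: str) -> int:
    """Count occurrences of a named motif in a digraph.

    Supported labels: ``edges``, ``mutual``, ``asym`` (dyads), any triad
    label (``201``, ``021C``, ...; also accepted with a ``triad_``
    prefix), ``instar_s`` / ``outstar_s`` (s arcs converging on / leaving
    one node) and ``cycle_3`` (cyclic triples).
    """
    _require_directed(g)
    a = g.adjacency.astype(np.int64)
    if label == "edges":
        return int(a.sum())
    if label in ("mutual", "asym"):
        m, s, _ = dyad_census(g)
        return m if label == "mutual" else s
    lab = label.removeprefix("triad_")
    if lab in TRIAD_LABELS:
        return triad_census(g).counts[lab]
    if label.startswith(("instar_", "outstar_")):
        s = int(label.split("_")[1])
        deg = a.sum(0) if label.startswith("instar_") else a.sum(1)
        return int(sum(comb(int(d), s) for d in deg))
    if label == "cycle_3":
        return int(np.trace(a @ a @ a)) // 3
    raise ValueError(f"unknown motif label {label!r}")


def functional_content(label: str) -> dict[str, int]:
    """Connected sub-digraphs (functional motifs) contained in a structural
    triad: counts of connected dyads and triads over all arc subsets of a
    representative of ``label``."""
    lab = label.removeprefix("triad_")
    if lab not in TRIAD_LABELS:
        raise ValueError(f"unknown triad label {label!r}")
    code = _ANCHORS[lab]
    arcs = [p for bit, p in enumerate(_PAIRS) if code >> bit & 1]
    out: dict[str, int] = {}
    for r in range(1, len(arcs) + 1):
        for subset in combinations(arcs, r):
            nodes = {x for arc in subset for x in arc}
            if len(nodes) == 2:
                sub_lab = "mutual" if len(subset) == 2 else "asym"
            else:
                sub_code = 0
                for bit, p in enumerate(_PAIRS):
                    if p in subset:
                        sub_code |= 1 << bit
                sub_lab = TRIAD_LABELS[_TRIAD_LOOKUP[sub_code]]
                if sub_lab in ("003", "012", "102"):
                    continue  # not weakly connected on 3 nodes
            out[sub_lab] = out.get(sub_lab, 0) + 1
    return out


# ---------------------------------------------------------------------------
# motif significance against surrogates


def directed_gnp(N: int, p: float, seed: int | None = None) -> Graph:
    """Directed Erdos-Renyi digraph: each ordered pair holds an arc with
    probability p."""
    rng = np.random.default_rng(seed)
    a = (rng.random((N, N)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    return Graph(a, directed=True, provenance={"generator": "directed_gnp", "p": p, "seed": seed})


@dataclass
class MotifSignificance:
    motif: str
    observed: int
    surrogate_mean: float
    surrogate_sd: float
    z: float  # nan when the surrogate distribution is degenerate
    p_two_sided: float
    ensemble: str
    n_surrogates: int


def motif_significance(
    g: Graph,
    motifs: list[str],
    ensemble: str = "erdos_renyi_matched_k",
    n_surrogates: int = 200,
    seed: int | None = None,
) -> list[MotifSignificance]:
    """z-scores and empirical two-sided p-values of motif counts against a
    surrogate ensemble.

    ``erdos_renyi_matched_k`` draws digraphs whose arc probability matches
    the observed arc density (so the surrogate average degree matches the
    empirical network); ``degree_preserving`` rewires the observed digraph
    keeping in- and out-degree sequences.
    """
    _require_directed(g)
    rng = np.random.default_rng(seed)
    observed = {m: count_motif(g, m) for m in motifs}
    N = g.n_nodes
    arc_density = g.n_edges / (N * (N - 1))
    sims = {m: np.empty(n_surrogates) for m in motifs}
    for r in range(n_surrogates):
        s_seed = int(rng.integers(2**31))
        if ensemble == "erdos_renyi_matched_k":
            s = directed_gnp(N, arc_density, seed=s_seed)
        elif ensemble == "degree_preserving":
            s = rewire_preserving_degrees(g, seed=s_seed)
        else:
            raise ValueError(f"unknown ensemble {ensemble!r}")
        for m in motifs:
            sims[m][r] = count_motif(s, m)
    results = []
    for m in motifs:
        vals = sims[m]
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        obs = observed[m]
        z = (obs - mean) / sd if sd > 0 else float("nan")
        p_hi = (1 + np.sum(vals >= obs)) / (1 + n_surrogates)
        p_lo = (1 + np.sum(vals <= obs)) / (1 + n_surrogates)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        results.append(
            MotifSignificance(m, obs, mean, sd, z, float(p), ensemble, n_surrogates)
        )
    return results
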