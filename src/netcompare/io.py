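"""File I/O and the synthetic connectivity-matrix generator.

Square matrices are read from CSV/TSV (optional header row / label
column); graphs are written as CSV matrices, tab-separated edge lists or
GraphML.  The synthetic generator emulates sensor-level functional
connectivity: a planted topology (e.g. a small-world graph) expressed as
a symmetric matrix of connection strengths in [0, 1], with a tunable
global offset that mimics between-condition differences in overall
connectivity level, plus additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .construction import ConnectivityMatrix
from .generators import GeneratorSpec
from .graph import Graph

__all__ = [
    "read_matrix",
    "read_adjacency",
    "read_connectivity",
    "write_graph",
    "SyntheticConnectivitySpec",
    "synth_connectivity",
]


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square numeric matrix from CSV/TSV, detecting an optional
    header row and label column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    labels = None

    def numeric(df: pd.DataFrame) -> np.ndarray | None:
        try:
            vals = df.astype(float).to_numpy()
        except (ValueError, TypeError):
            return None
        return vals

    vals = numeric(raw)
    if vals is None:
        # header row, label column, or both: accept the first trimming that
        # yields a square numeric matrix
        candidates = [
            (raw.iloc[1:, :], raw.iloc[0, :].tolist()),      # header row
            (raw.iloc[1:, 1:], raw.iloc[0, 1:].tolist()),    # header + labels
            (raw.iloc[:, 1:], raw.iloc[:, 0].tolist()),      # label column
        ]
        for body, labs in candidates:
            v = numeric(body)
            if v is not None and v.shape[0] == v.shape[1] and v.size > 0:
                vals, labels = v, [str(x) for x in labs]
                break
    if vals is None:
        raise ValueError(f"{path}: matrix entries are not numeric")
    if np.any(np.isnan(vals)):
        raise ValueError(f"{path}: matrix contains NaN entries")
    if vals.shape[0] != vals.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {vals.shape}")
    return vals, labels


def read_adjacency(path: str | Path, directed: bool = False, weighted: bool = False) -> Graph:
    """Read an adjacency matrix as a validated :class:`Graph`."""
    vals, _ = read_matrix(path)
    if not directed and not np.allclose(vals, vals.T):
        raise ValueError(f"{path}: asymmetric matrix but directed=False")
    if np.any(np.diagonal(vals) != 0):
        raise ValueError(f"{path}: nonzero diagonal (self-loops are forbidden)")
    return Graph(vals, directed=directed, weighted=weighted)


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    """Read a symmetric connectivity matrix (diagonal ignored)."""
    vals, labels = read_matrix(path)
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(vals, node_labels=labels)


def write_graph(g: Graph, path: str | Path, format: str = "csv_matrix") -> None:
    """Write a graph deterministically as ``csv_matrix``, ``edge_list``
    (source<TAB>target<TAB>weight, sorted) or ``graphml``."""
    path = Path(path)
    if format == "csv_matrix":
        np.savetxt(path, g.adjacency, delimiter=",", fmt="%.12g")
    elif format == "edge_list":
        with open(path, "w") as fh:
            for i, j, w in g.edge_list():
                fh.write(f"{i}\t{j}\t{w:.12g}\n")
    elif format == "graphml":
        nxg = g.to_networkx()
        nx.relabel_nodes(nxg, {n: str(n) for n in nxg.nodes()}, copy=False)
        nx.write_graphml(nxg, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# synthetic connectivity


@dataclass
class SyntheticConnectivitySpec:
    """Recipe for a synthetic symmetric connectivity matrix.

    ``base_strength`` separates planted edges from background;
    ``global_offset`` shifts the whole matrix, emulating conditions that
    differ in overall connectivity; ``noise_sd`` is the SD of additive
    Gaussian noise.  Entries are clipped to [0, 1]."""

    N: int
    planted_topology: GeneratorSpec
    base_strength: float = 0.6
    noise_sd: float = 0.05
    global_offset: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.base_strength <= 1.0:
            raise ValueError("base_strength must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_topology.N != self.N:
            raise ValueError("planted topology N must match spec N")


def synth_connectivity(spec: SyntheticConnectivitySpec) -> ConnectivityMatrix:
    """Symmetric connectivity matrix with a planted topology.

    entries = base_strength * edge_indicator + global_offset + noise,
    symmetrized, clipped to [0, 1], zero diagonal.  With noise_sd well
    below base_strength the planted graph is recoverable by thresholding.
    """
    rng = np.random.default_rng(spec.seed)
    planted = spec.planted_topology.sample(seed=int(rng.integers(2**31)))
    a = (planted.adjacency != 0).astype(float)
    noise = rng.normal(0.0, spec.noise_sd, size=a.shape)
    noise = (noise + noise.T) / np.sqrt(2.0)  # symmetric, SD preserved
    vals = spec.base_strength * a + spec.global_offset + noise
    vals = np.clip(vals, 0.0, 1.0)
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(vals)
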