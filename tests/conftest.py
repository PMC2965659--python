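import numpy as np
import pytest

from netcompare.graph import Graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def complete_graph(n: int, directed: bool = False) -> Graph:
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return Graph(a, directed=directed)


def star_graph(n: int) -> Graph:
    a = np.zeros((n, n), dtype=np.int8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return Graph(a)


def random_graph(n: int, p: float, rng: np.random.Generator) -> Graph:
    upper = np.triu(rng.random((n, n)) < p, 1)
    return Graph((upper | upper.T).astype(np.int8))


def random_digraph(n: int, p: float, rng: np.random.Generator) -> Graph:
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    return Graph(a, directed=True)


# -- independent brute-force oracles ---------------------------------------


def bfs_path_oracle(g: Graph) -> tuple[float, float]:
    """Mean shortest-path length over reachable ordered pairs, by explicit
    breadth-first search."""
    n = g.n_nodes
    adj = [list(np.nonzero(g.adjacency[i])[0]) for i in range(n)]
    total, count = 0, 0
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t, d in dist.items():
            if t != s:
                total += d
                count += 1
    if count == 0:
        raise ValueError("no reachable pairs")
    return total / count, count / (n * (n - 1))


def triangle_clustering_oracle(g: Graph) -> float:
    """Average clustering by explicit neighbor-pair enumeration."""
    n = g.n_nodes
    a = g.adjacency
    vals = []
    for i in range(n):
        nbrs = list(np.nonzero(a[i])[0])
        d = len(nbrs)
        if d < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for x in range(d) for y in range(x + 1, d) if a[nbrs[x], nbrs[y]]
        )
        vals.append(links / (d * (d - 1) / 2))
    return float(np.mean(vals))
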