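"""Graph construction and random-walk stimulus sequences.

All stimulus graphs are connected, 4-regular, undirected graphs on 15 nodes:
a modular graph (three 5-node clusters arranged in a ring), a ring lattice
(neighbors at circular distance 1 and 2), and uniformly sampled connected
4-regular random graphs.  Node sequences are generated by unbiased random
walks; because the graphs are regular, the stationary distribution over nodes
is uniform and every edge is traversed with equal long-run frequency, which is
what matches one-step transition probabilities within and between clusters.

Nodes are 0-based internally; file I/O uses 1-based labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

N_NODES = 15


@dataclass(frozen=True)
class Graph:
    """Undirected stimulus graph.

    Attributes
    ----------
    adjacency : (n, n) symmetric 0/1 array with zero diagonal.
    cluster_of : optional mapping node -> cluster label (modular graph only).
    """

    adjacency: np.ndarray
    cluster_of: dict[int, int] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not nx.is_connected(nx.from_numpy_array(a)):
            raise ValueError("graph must be connected")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def neighbors(self, u: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[u])

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] > 0
        return list(zip(iu[mask].tolist(), ju[mask].tolist()))

    def is_cross_cluster(self, u: int, v: int) -> bool:
        if self.cluster_of is None:
            raise ValueError("graph has no cluster labels")
        return self.cluster_of[u] != self.cluster_of[v]


@dataclass(frozen=True)
class Walk:
    """A random-walk node sequence on a graph (one task stage)."""

    nodes: np.ndarray
    graph: Graph
    stage: int = 1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=np.int64)
        a = self.graph.adjacency
        if len(nodes) > 1 and not np.all(a[nodes[:-1], nodes[1:]] > 0):
            raise ValueError("walk contains a non-edge step")
        object.__setattr__(self, "nodes", nodes)

    def __len__(self) -> int:
        return len(self.nodes)


def make_modular_graph() -> Graph:
    """Three 5-node clusters in a ring.

    Within each cluster all pairs are connected except the two boundary nodes;
    each boundary node carries exactly one cross-cluster edge to a boundary
    node of an adjacent cluster.  Every node has degree 4, so one-step
    transition probabilities are matched (0.25) on every edge, including the
    three cross-cluster edges.
    """
    n = N_NODES
    a = np.zeros((n, n), dtype=np.int8)
    cluster_of = {}
    # nodes c*5 .. c*5+4; boundary nodes are c*5 (entry) and c*5+4 (exit)
    for c in range(3):
        lo = c * 5
        for i in range(5):
            cluster_of[lo + i] = c
            for j in range(i + 1, 5):
                a[lo + i, lo + j] = a[lo + j, lo + i] = 1
        a[lo, lo + 4] = a[lo + 4, lo] = 0  # boundary pair not connected
    for c in range(3):  # ring of clusters: exit of c -> entry of c+1
        u = c * 5 + 4
        v = ((c + 1) % 3) * 5
        a[u, v] = a[v, u] = 1
    return Graph(a, cluster_of=cluster_of)


def make_lattice_graph() -> Graph:
    """15-node ring lattice: each node adjacent to circular distances 1 and 2."""
    n = N_NODES
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for d in (1, 2):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1
    return Graph(a)


def make_random_graph(seed: int, max_attempts: int = 100) -> Graph:
    """Connected 4-regular random graph on 15 nodes, uniform up to rejection.

    Resamples from networkx's regular-graph sampler until connected;
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        g = nx.random_regular_graph(4, N_NODES, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            a = nx.to_numpy_array(g, nodelist=range(N_NODES), dtype=np.int8)
            return Graph(a)
    raise RuntimeError(
        f"no connected 4-regular graph found in {max_attempts} attempts"
    )


def random_walk(graph: Graph, n_trials: int, seed: int, stage: int = 1) -> Walk:
    """Unbiased random walk; start node uniform, each step uniform over neighbors."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    nbrs = [graph.neighbors(u) for u in range(graph.n_nodes)]
    deg = np.array([len(nb) for nb in nbrs])
    nodes = np.empty(n_trials, dtype=np.int64)
    nodes[0] = rng.integers(graph.n_nodes)
    u = rng.random(n_trials)  # pre-drawn uniforms keep the hot loop cheap
    for t in range(1, n_trials):
        prev = nodes[t - 1]
        nodes[t] = nbrs[prev][int(u[t] * deg[prev])]
    return Walk(nodes=nodes, graph=graph, stage=stage, rng_seed=seed)


def transition_matrix(graph: Graph) -> np.ndarray:
    """True one-step walk kernel: adjacency rows normalized by degree."""
    a = graph.adjacency.astype(float)
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("graph has an isolated node")
    return a / deg[:, None]


def empirical_transition_matrix(nodes: np.ndarray, n_nodes: int = N_NODES) -> np.ndarray:
    """Row-normalized transition counts of an observed node sequence.

    Rows for nodes never seen as a predecessor are set uniform.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    counts = np.zeros((n_nodes, n_nodes))
    np.add.at(counts, (nodes[:-1], nodes[1:]), 1.0)
    out = counts.sum(axis=1)
    t = np.full((n_nodes, n_nodes), 1.0 / n_nodes)
    seen = out > 0
    t[seen] = counts[seen] / out[seen, None]
    return t


def write_edgelist(graph: Graph, path: str | Path) -> None:
    """Edge-list TSV (1-based) with an optional JSON sidecar of cluster labels."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u + 1}\t{v + 1}\n")
    if graph.cluster_of is not None:
        sidecar = path.with_suffix(path.suffix + ".clusters.json")
        with open(sidecar, "w") as fh:
            json.dump({str(k + 1): v for k, v in graph.cluster_of.items()}, fh)


def read_edgelist(path: str | Path, n_nodes: int = N_NODES) -> Graph:
    path = Path(path)
    a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    with open(path) as fh:
        for line in fh:
            u, v = (int(x) - 1 for x in line.split())
            a[u, v] = a[v, u] = 1
    cluster_of = None
    sidecar = path.with_suffix(path.suffix + ".clusters.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            cluster_of = {int(k) - 1: v for k, v in json.load(fh).items()}
    return Graph(a, cluster_of=cluster_of)


GRAPH_FAMILIES = ("modular", "lattice", "random")


def make_graph(family: str, seed: int = 0) -> Graph:
    """Dispatch constructor by family name ('modular', 'lattice', 'random')."""
    if family == "modular":
        return make_modular_graph()
    if family == "lattice":
        return make_lattice_graph()
    if family == "random":
        return make_random_graph(seed)
    raise ValueError(f"unknown graph family: {family!r}")
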