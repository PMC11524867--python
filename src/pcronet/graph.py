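"""Simple undirected graphs, Erdős–Rényi generation, and edge-list / GraphML I/O.

The graph model used throughout the package is a *simple* undirected graph on
dense integer node ids ``0..n_nodes-1``.  Isolated nodes are first-class
citizens (an id with no incident edges), because naturally isolated nodes are
one of the node classes the rewiring operation acts on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "ERRNParams",
    "GraphParseError",
    "generate_errn",
    "degree_sequence",
    "read_graph",
    "write_graph",
]


class GraphParseError(ValueError):
    """Raised when a graph file is malformed (bad line, self-loop, bad id)."""


def _normalize_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph on node ids ``0..n_nodes-1``.

    Edges are stored once as sorted ``(u, v)`` tuples with ``u < v``; no
    self-loops, no parallel edges.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError(f"n_nodes must be >= 1, got {self.n_nodes}")
        edges = frozenset(_normalize_edge(u, v) for u, v in self.edges)
        object.__setattr__(self, "edges", edges)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) is not allowed")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(
                    f"edge ({u},{v}) out of range for n_nodes={self.n_nodes}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: int) -> int:
        return sum(1 for u, v in self.edges if u == node or v == node)

    def degrees(self) -> np.ndarray:
        """Degree of every node as an integer array of length ``n_nodes``."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def average_degree(self) -> float:
        """Realized average degree 2L/N of this graph."""
        return 2.0 * self.n_edges / self.n_nodes

    def neighbors(self, node: int) -> set[int]:
        out: set[int] = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def has_edge(self, u: int, v: int) -> bool:
        return _normalize_edge(u, v) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        """Convert a networkx graph; node labels must be 0..N-1 integers."""
        n = g.number_of_nodes()
        relabel = {node: int(node) for node in g.nodes}
        if sorted(relabel.values()) != list(range(n)):
            raise ValueError("node labels must be the dense integers 0..N-1")
        return cls(n, frozenset(_normalize_edge(int(u), int(v)) for u, v in g.edges))


@dataclass(frozen=True)
class ERRNParams:
    """Parameters of an Erdős–Rényi random network G(N, p).

    ``n_nodes`` is the node count N; ``connection_prob`` is the independent
    per-pair link probability P_ER.
    """

    n_nodes: int
    connection_prob: float

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0.0 <= self.connection_prob <= 1.0:
            raise ValueError("connection_prob must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def expected_edges(self) -> float:
        """Expected edge count P_ER * N(N-1)/2."""
        return self.connection_prob * self.n_pairs


def pair_index_arrays(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column ids of the N(N-1)/2 unordered pairs, in (i<j) order."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return iu.astype(np.int64), ju.astype(np.int64)


def generate_errn(params: ERRNParams, seed: int | np.random.Generator) -> Graph:
    """Draw one Erdős–Rényi graph: each unordered pair is linked with P_ER.

    ``seed`` may be an integer or an already-constructed numpy Generator;
    identical integer seeds produce identical graphs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    iu, ju = pair_index_arrays(params.n_nodes)
    mask = rng.random(params.n_pairs) < params.connection_prob
    edges = frozenset(zip(iu[mask].tolist(), ju[mask].tolist()))
    return Graph(params.n_nodes, edges)


def degree_sequence(g: Graph) -> list[int]:
    """Degrees by node id; the sum equals twice the edge count."""
    return g.degrees().tolist()


def write_graph(g: Graph, path, fmt: str = "edgelist") -> None:
    """Write a graph as a plain-text edge list or as GraphML.

    The edge-list dialect is one ``u v`` pair per line (0-based ids), ``#``
    comments, and a ``#nodes N`` header so trailing isolated nodes survive a
    round-trip.
    """
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"#nodes {g.n_nodes}\n")
            for u, v in sorted(g.edges):
                fh.write(f"{u} {v}\n")
    elif fmt == "graphml":
        nx.write_graphml(g.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph format: {fmt!r}")


def read_graph(path, fmt: str = "edgelist") -> Graph:
    """Read a graph written by :func:`write_graph`.

    Duplicate edges are deduplicated with a warning; self-loops and malformed
    lines raise :class:`GraphParseError` naming the offending line.
    """
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return Graph.from_networkx(nx.relabel_nodes(g, {n: int(n) for n in g.nodes}))
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format: {fmt!r}")

    edges: set[tuple[int, int]] = set()
    n_declared: int | None = None
    max_id = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                parts = stripped[1:].split()
                if len(parts) == 2 and parts[0] == "nodes":
                    try:
                        n_declared = int(parts[1])
                    except ValueError as exc:
                        raise GraphParseError(
                            f"line {lineno}: bad node count {parts[1]!r}"
                        ) from exc
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise GraphParseError(f"line {lineno}: expected two ids, got {stripped!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphParseError(f"line {lineno}: non-integer id in {stripped!r}") from exc
            if u < 0 or v < 0:
                raise GraphParseError(f"line {lineno}: negative node id in {stripped!r}")
            if u == v:
                raise GraphParseError(f"line {lineno}: self-loop {u}-{v} not allowed")
            edge = _normalize_edge(u, v)
            if edge in edges:
                logger.warning("%s line %d: duplicate edge %s-%s ignored", path, lineno, u, v)
            edges.add(edge)
            max_id = max(max_id, u, v)

    n_nodes = n_declared if n_declared is not None else max_id + 1
    if n_nodes < 1:
        raise GraphParseError("file declares no nodes and lists no edges")
    if max_id >= n_nodes:
        raise GraphParseError(
            f"edge id {max_id} out of range for declared node count {n_nodes}"
        )
    return Graph(n_nodes, frozenset(edges))
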