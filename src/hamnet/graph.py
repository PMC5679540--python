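"""Undirected simple graphs, edge-list / partition I/O, and network statistics.

Node identifiers are opaque strings: a token that looks like an integer is
kept as the string it was read as, so labels survive a round trip through
output partition tables unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

logger = logging.getLogger(__name__)

Node = str
Edge = tuple[Node, Node]


def edge_key(i: Node, j: Node) -> Edge:
    """Canonical unordered edge key: endpoints sorted as strings."""
    return (i, j) if i <= j else (j, i)


class Graph:
    """Undirected simple graph stored as neighbor sets.

    Invariants maintained by construction: adjacency is symmetric, there are
    no self-loops and no multi-edges, and ``sum(degrees) == 2 * n_edges``.
    """

    __slots__ = ("_adj",)

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[Node] = ()):
        self._adj: dict[Node, set[Node]] = {}
        for v in nodes:
            self.add_node(v)
        for i, j in edges:
            self.add_edge(i, j)

    def add_node(self, v: Node) -> None:
        self._adj.setdefault(v, set())

    def add_edge(self, i: Node, j: Node) -> None:
        if i == j:
            raise ValueError(f"self-loop on node {i!r} not allowed")
        self._adj.setdefault(i, set()).add(j)
        self._adj.setdefault(j, set()).add(i)

    # -- basic queries -------------------------------------------------
    @property
    def nodes(self) -> set[Node]:
        return set(self._adj)

    def neighbors(self, v: Node) -> set[Node]:
        return self._adj[v]

    def degree(self, v: Node) -> int:
        return len(self._adj[v])

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_node(self, v: Node) -> bool:
        return v in self._adj

    def has_edge(self, i: Node, j: Node) -> bool:
        return i in self._adj and j in self._adj[i]

    def edges(self) -> Iterator[Edge]:
        """All edges as canonical (min, max) keys, in sorted order."""
        for i in sorted(self._adj):
            for j in sorted(self._adj[i]):
                if i < j:
                    yield (i, j)

    def subgraph(self, keep: Iterable[Node]) -> "Graph":
        keep = set(keep)
        g = Graph(nodes=keep)
        for i, j in self.edges():
            if i in keep and j in keep:
                g.add_edge(i, j)
        return g

    def components(self) -> list[set[Node]]:
        """Connected components, sorted by (-size, min node id)."""
        seen: set[Node] = set()
        comps: list[set[Node]] = []
        for start in self._adj:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for u in self._adj[v]:
                    if u not in comp:
                        comp.add(u)
                        stack.append(u)
            seen |= comp
            comps.append(comp)
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    def is_connected(self) -> bool:
        return self.n_nodes <= 1 or len(self.components()) == 1

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(|V|={self.n_nodes}, |E|={self.n_edges})"


@dataclass
class Partition:
    """A complete, disjoint node -> community-label assignment."""

    assignment: dict[Node, str]

    @property
    def communities(self) -> dict[str, set[Node]]:
        out: dict[str, set[Node]] = {}
        for v, c in self.assignment.items():
            out.setdefault(c, set()).add(v)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def nodes(self) -> set[Node]:
        return set(self.assignment)

    @classmethod
    def from_communities(cls, comms: Iterable[Iterable[Node]]) -> "Partition":
        assignment: dict[Node, str] = {}
        for idx, members in enumerate(comms):
            for v in members:
                if v in assignment:
                    raise ValueError(f"node {v!r} assigned to two communities")
                assignment[v] = str(idx)
        return cls(assignment)

    def relabel_canonical(self) -> "Partition":
        """Rename community labels to 0..M-1 in order of smallest member."""
        groups = sorted(self.communities.values(), key=min)
        return Partition.from_communities(groups)

    def __eq__(self, other: object) -> bool:
        """Equality up to community label renaming."""
        if not isinstance(other, Partition):
            return NotImplemented
        if set(self.assignment) != set(other.assignment):
            return False
        return (frozenset(frozenset(c) for c in self.communities.values())
                == frozenset(frozenset(c) for c in other.communities.values()))


@dataclass
class NetworkStats:
    """Summary statistics of a (connected) graph.

    ``assortativity`` is the Pearson correlation of degrees over the 2|E|
    directed edge ends; it is ``None`` (undefined) on degree-regular graphs,
    where the edge-end degree variance vanishes.
    """

    n_nodes: int
    n_edges: int
    mean_clustering: float
    mean_degree: float
    max_degree: int
    assortativity: Optional[float]


# ---------------------------------------------------------------------------
# I/O

def read_edge_list(path, directed_ok: bool = True) -> Graph:
    """Read a plain-text edge list: two whitespace-separated node tokens per
    line; ``#`` comment lines and blank lines are ignored, as are extra
    tokens on a line.  Duplicate and reversed-duplicate lines collapse to a
    single edge; self-loop lines are dropped with a warning.
    """
    g = Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two node tokens, got {line!r}"
                )
            i, j = tokens[0], tokens[1]
            if i == j:
                logger.warning("%s: line %d: dropping self-loop on %r", path, lineno, i)
                g.add_node(i)
                continue
            g.add_edge(i, j)
    return g


def write_edge_list(g: Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in g.edges():
            fh.write(f"{i}\t{j}\n")


def read_partition(path) -> Partition:
    """Read a two-column node / community-label table (TSV or whitespace)."""
    assignment: dict[Node, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected node and community label"
                )
            v, c = tokens[0], tokens[1]
            if v in assignment and assignment[v] != c:
                raise ValueError(
                    f"{path}: line {lineno}: node {v!r} assigned to both "
                    f"{assignment[v]!r} and {c!r}"
                )
            assignment[v] = c
    return Partition(assignment)


def write_partition(p: Partition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in sorted(p.assignment):
            fh.write(f"{v}\t{p.assignment[v]}\n")


# ---------------------------------------------------------------------------
# Analysis

def giant_component(g: Graph) -> Graph:
    """Induced subgraph on the largest connected component (GCC).

    Size ties are broken in favour of the component containing the smallest
    node identifier.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph has no giant component")
    return g.subgraph(g.components()[0])


def local_clustering(g: Graph, v: Node) -> float:
    """Fraction of neighbor pairs of v that are themselves connected.

    Nodes of degree < 2 have no neighbor pair and contribute 0.
    """
    nbrs = g.neighbors(v)
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = 0
    for u in nbrs:
        links += len(g.neighbors(u) & nbrs)
    return links / (k * (k - 1))


def degree_assortativity(g: Graph) -> Optional[float]:
    """Pearson degree correlation over directed edge ends (Newman's r).

    Returns None on degree-regular graphs (zero edge-end variance).
    """
    if g.n_edges == 0:
        return None
    sx = sxx = sxy = 0.0
    m2 = 2 * g.n_edges
    for i, j in g.edges():
        ki, kj = g.degree(i), g.degree(j)
        sx += ki + kj
        sxx += ki * ki + kj * kj
        sxy += 2 * ki * kj
    mean = sx / m2
    var = sxx / m2 - mean * mean
    if var <= 1e-15 * max(1.0, mean * mean):
        return None
    cov = sxy / m2 - mean * mean
    return cov / var


def network_stats(g: Graph) -> NetworkStats:
    """Node/edge counts, mean clustering, mean/max degree and assortativity."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    degs = [g.degree(v) for v in g.nodes]
    return NetworkStats(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        mean_clustering=math.fsum(local_clustering(g, v) for v in g.nodes) / g.n_nodes,
        mean_degree=2 * g.n_edges / g.n_nodes,
        max_degree=max(degs),
        assortativity=degree_assortativity(g),
    )
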