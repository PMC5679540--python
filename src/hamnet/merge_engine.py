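"""Rule-based arc-merging: the original-network phase.

Five rules act on an edge (x, y) depending on whether its endpoints already
belong to a super-node:

* R1 — both unmerged: create a super-node containing both endpoints.
* R2/R3 — exactly one endpoint merged: absorb the free endpoint into the
  existing super-node (optionally retain it as its own super-node instead).
* R4 — both unmerged: retain each endpoint as its own super-node and connect
  them with a super-edge.
* R5 — both already merged: never merge; if they sit in different
  super-nodes, accumulate the super-edge between them (summed weight and
  original-edge count); if in the same super-node, count the edge as
  internal.

Three strategies fix which rule handles the both-unmerged case while a
sorted edge class is swept:

* T1 (community creating, weighted edges) uses R1 — weighted edges seed
  communities.
* T2 (structure maintenance, bridge edges) uses R4 — bridge endpoints are
  retained so that small communities joined by bridges are not swallowed.
* T3 (sink shrinking, sink edges) merges every degree-1 endpoint into its
  neighbor's super-node, bootstrapping a super-node for a still-unmerged
  hub first; an isolated degree-1/degree-1 dyad becomes one super-node.

The same machinery runs unchanged on the coarse graph in the super-node
phase: there a "node" is a super-node carrying its own internal edge count
and summed degree, and an "edge" contributes its accumulated original-edge
count instead of 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional

from .edge_classifier import EdgeClasses, classify_edges
from .graph import Graph, Node, Partition
from .similarity import WeightedEdgeMap

LevelNode = Hashable


@dataclass
class SuperNode:
    """A community under construction: member original nodes, internal
    original-edge count l, and summed original degree d."""

    id: int
    members: set[Node]
    l: int
    d: int


@dataclass
class SuperEdge:
    """Aggregated connection between two super-nodes: summed original edge
    weights w_hat and original-edge count e_count; delta_q is filled in by
    the super-node phase."""

    endpoints: tuple[int, int]
    w_hat: float
    e_count: int
    delta_q: Optional[float] = None


class MergeState:
    """Working state of a single merging sweep over one level of the
    hierarchy.

    ``node_info`` maps each level-node to its (members, l, d) payload:
    for the original graph each node is ({itself}, 0, its degree); for a
    coarse graph each node is an existing super-node.
    """

    def __init__(self, node_info: Mapping[LevelNode, tuple[set[Node], int, int]]):
        self._info = dict(node_info)
        self.assignment: dict[LevelNode, int] = {}
        self.supernodes: dict[int, SuperNode] = {}
        self.superedges: dict[tuple[int, int], SuperEdge] = {}
        self._ids = itertools.count()

    # -- low-level state transitions ----------------------------------
    def _create(self, members_of: list[LevelNode], internal: int) -> SuperNode:
        sid = next(self._ids)
        members: set[Node] = set()
        l = internal
        d = 0
        for x in members_of:
            mem, lx, dx = self._info[x]
            members |= mem
            l += lx
            d += dx
            self.assignment[x] = sid
        sn = SuperNode(sid, members, l, d)
        self.supernodes[sid] = sn
        return sn

    def _absorb(self, sid: int, x: LevelNode, internal: int) -> None:
        mem, lx, dx = self._info[x]
        sn = self.supernodes[sid]
        sn.members |= mem
        sn.l += lx + internal
        sn.d += dx
        self.assignment[x] = sid

    def _connect(self, a: int, b: int, w: float, e_count: int) -> None:
        key = (a, b) if a < b else (b, a)
        se = self.superedges.get(key)
        if se is None:
            self.superedges[key] = SuperEdge(key, w, e_count)
        else:
            se.w_hat += w
            se.e_count += e_count

    # -- the five rules -----------------------------------------------
    def apply_rule(
        self,
        x: LevelNode,
        y: LevelNode,
        w: float,
        e_count: int,
        strategy: str,
        bridge_retain: bool = False,
    ) -> str:
        """Apply the strategy-selected rule to edge (x, y); returns the rule
        that fired ("R1".."R5")."""
        if strategy not in ("T1", "T2", "T3"):
            raise ValueError(f"unknown strategy {strategy!r}")
        if x not in self._info or y not in self._info:
            raise KeyError(f"edge ({x!r}, {y!r}) references unknown node")
        ax = self.assignment.get(x)
        ay = self.assignment.get(y)
        if ax is None and ay is None:
            if strategy == "T1":
                self._create([x, y], internal=e_count)
                return "R1"
            if strategy == "T2":
                sx = self._create([x], internal=0)
                sy = self._create([y], internal=0)
                self._connect(sx.id, sy.id, w, e_count)
                return "R4"
            return "R5"  # T3 defers; strategy_T3 bootstraps explicitly
        if ax is None or ay is None:
            free, anchored = (x, ay) if ax is None else (y, ax)
            if strategy == "T2" and bridge_retain:
                sn = self._create([free], internal=0)
                self._connect(sn.id, anchored, w, e_count)
                return "R2" if ax is None else "R3"
            self._absorb(anchored, free, internal=e_count)
            return "R2" if ax is None else "R3"
        if ax == ay:
            self.supernodes[ax].l += e_count
        else:
            self._connect(ax, ay, w, e_count)
        return "R5"


@dataclass
class SuperNetwork:
    """One level of the coarsening hierarchy, plus the original graph's
    edge count needed by modularity arithmetic."""

    supernodes: dict[int, SuperNode]
    superedges: dict[tuple[int, int], SuperEdge]
    total_edges: int

    def partition(self) -> Partition:
        """Flatten super-node membership into an original-node partition."""
        assignment = {}
        for sn in self.supernodes.values():
            for v in sn.members:
                assignment[v] = str(sn.id)
        return Partition(assignment)

    @property
    def n_supernodes(self) -> int:
        return len(self.supernodes)


def strategy_T1(
    state: MergeState, edges, weights, e_counts=None, bridge_retain: bool = False
) -> None:
    """Community-creating sweep over presorted weighted edges (R1/R2/R3/R5)."""
    for e in edges:
        c = 1 if e_counts is None else e_counts[e]
        state.apply_rule(e[0], e[1], weights[e], c, "T1")


def strategy_T2(
    state: MergeState, edges, weights, e_counts=None, bridge_retain: bool = False
) -> None:
    """Structure-maintenance sweep over presorted bridge edges (R2/R3/R4/R5)."""
    for e in edges:
        c = 1 if e_counts is None else e_counts[e]
        state.apply_rule(e[0], e[1], weights[e], c, "T2", bridge_retain)


def strategy_T3(state: MergeState, edges, weights, degrees) -> None:
    """Sink-shrinking sweep (R2/R3/R5): every degree-1 endpoint is merged
    into its neighbor's super-node.

    If the non-leaf endpoint is still unmerged (all of its edges are sinks,
    e.g. a star hub) a super-node is bootstrapped for it first; a 2-node
    component of two degree-1 nodes becomes a single super-node.
    """
    for x, y in edges:
        ax = state.assignment.get(x)
        ay = state.assignment.get(y)
        if ax is None and ay is None:
            if degrees[x] == 1 and degrees[y] == 1:
                state._create([x, y], internal=1)
                continue
            hub = x if degrees[x] > 1 else y
            state._create([hub], internal=0)
        state.apply_rule(x, y, weights[(x, y) if x < y else (y, x)], 1, "T3")


def original_phase(
    g: Graph,
    wmap: WeightedEdgeMap,
    w_threshold: float = 0.0,
    bridge_retain: bool = False,
) -> tuple[SuperNetwork, Partition]:
    """Run classify -> T1 -> T2 -> T3 on the original graph and return the
    level-1 super-node network plus the induced partition.

    Expects a connected graph (isolated single nodes become their own
    super-nodes so that a 1-node graph is handled gracefully).
    """
    classes = classify_edges(g, wmap, w_threshold)
    info = {v: ({v}, 0, g.degree(v)) for v in g.nodes}
    state = MergeState(info)
    strategy_T1(state, classes.weighted, wmap)
    strategy_T2(state, classes.bridge, wmap, bridge_retain=bridge_retain)
    degrees = {v: g.degree(v) for v in g.nodes}
    strategy_T3(state, classes.sink, wmap, degrees)
    for v in sorted(g.nodes):  # isolated nodes (no incident edge)
        if v not in state.assignment:
            state._create([v], internal=0)
    net = SuperNetwork(state.supernodes, state.superedges, g.n_edges)
    return net, net.partition()
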