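"""Iterative coarsening of the super-node network and the HAM main loop.

At each level every super-edge gets a merge gain

    dQ_ij = e_ij/|E| - (d_ij^2 - d_i^2 - d_j^2) / (4 |E|^2),   d_ij = d_i + d_j

(the exact change in modularity from merging the two communities, with |E|
always the original graph's edge count).  Super-edges with summed weight
w_hat > 0 AND dQ > 0 form the merge class and are processed by the
community-creating strategy in (dQ desc, w_hat desc) order; every other
super-edge only maintains structure (T2).  The loop stops when the merge
class is empty, when a level produces no merge, or when the modularity gain
of a level does not exceed ``epsilon``.

The gate on w_hat is what mitigates the resolution limit: two cliques
joined by a single zero-similarity bridge have dQ > 0 but w_hat = 0, so
modularity alone never forces them together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import Graph, Partition, giant_component
from .merge_engine import (
    MergeState,
    SuperEdge,
    SuperNetwork,
    original_phase,
    strategy_T1,
    strategy_T2,
)
from .quality import modularity
from .similarity import weight_edges

logger = logging.getLogger(__name__)


def delta_q(l_i: int, l_j: int, d_i: int, d_j: int, e_count: int, E_total: int) -> float:
    """Modularity gain from merging two communities joined by e_count edges.

    Algebraically equal to e_count/|E| - d_i*d_j / (2|E|^2); the internal
    edge counts cancel and are accepted only for interface symmetry.
    """
    if E_total <= 0:
        raise ValueError("E_total must be positive")
    d_ij = d_i + d_j
    return e_count / E_total - (d_ij * d_ij - d_i * d_i - d_j * d_j) / (4 * E_total * E_total)


def classify_super_edges(net: SuperNetwork) -> tuple[list[SuperEdge], list[SuperEdge]]:
    """Split super-edges into the ordered merge class (w_hat > 0 and dQ > 0)
    and the bypass class; fills in each super-edge's delta_q."""
    merge_class: list[SuperEdge] = []
    bypass: list[SuperEdge] = []
    sns = net.supernodes
    for se in net.superedges.values():
        a, b = se.endpoints
        se.delta_q = delta_q(
            sns[a].l, sns[b].l, sns[a].d, sns[b].d, se.e_count, net.total_edges
        )
        if se.w_hat > 0 and se.delta_q > 0:
            merge_class.append(se)
        else:
            bypass.append(se)
    merge_class.sort(key=lambda se: (-se.delta_q, -se.w_hat, se.endpoints))
    bypass.sort(
        key=lambda se: (-(sns[se.endpoints[0]].d + sns[se.endpoints[1]].d), se.endpoints)
    )
    return merge_class, bypass


def supernode_level(net: SuperNetwork) -> SuperNetwork:
    """Build the next coarsening level: T1 over the merge class, T2 over the
    bypass class, with refreshed l, d, w_hat and e_count."""
    merge_class, bypass = classify_super_edges(net)
    info = {sid: (sn.members, sn.l, sn.d) for sid, sn in net.supernodes.items()}
    state = MergeState(info)
    weights = {se.endpoints: se.w_hat for se in net.superedges.values()}
    e_counts = {se.endpoints: se.e_count for se in net.superedges.values()}
    strategy_T1(state, [se.endpoints for se in merge_class], weights, e_counts)
    strategy_T2(state, [se.endpoints for se in bypass], weights, e_counts)
    for sid in sorted(net.supernodes):  # isolated super-nodes carry over
        if sid not in state.assignment:
            state._create([sid], internal=0)
    return SuperNetwork(state.supernodes, state.superedges, net.total_edges)


@dataclass
class HAMResult:
    """Hierarchy of accepted levels with their partitions and Q values."""

    levels: list[tuple[Partition, float]]
    config: dict

    @property
    def final_partition(self) -> Partition:
        return self.levels[-1][0]

    @property
    def final_q(self) -> float:
        return self.levels[-1][1]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _run_connected(g: Graph, measure, w_threshold, epsilon, bridge_retain):
    wmap = weight_edges(g, measure)
    net, part = original_phase(g, wmap, w_threshold, bridge_retain)
    levels = [(part, modularity(g, part))]
    while True:
        merge_class, _ = classify_super_edges(net)
        if not merge_class:
            break
        nxt = supernode_level(net)
        if nxt.n_supernodes == net.n_supernodes:
            break
        part = nxt.partition()
        q = modularity(g, part)
        if q - levels[-1][1] <= epsilon:
            break
        levels.append((part, q))
        net = nxt
    return levels


def run_ham(
    g: Graph,
    measure: str = "min",
    w_threshold: float = 0.0,
    epsilon: float = 0.0,
    bridge_retain: bool = False,
    on_disconnected: str = "gcc",
) -> HAMResult:
    """Run the full two-phase algorithm and return the level hierarchy.

    ``on_disconnected`` chooses what to do with a disconnected input:
    "gcc" (default) analyses the giant component with a warning,
    "components" analyses every component independently and unions the
    partitions, "error" raises.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    config = {
        "measure": measure,
        "w_threshold": w_threshold,
        "epsilon": epsilon,
        "bridge_retain": bridge_retain,
    }
    comps = g.components()
    if len(comps) > 1:
        if on_disconnected == "error":
            raise ValueError(f"graph is disconnected ({len(comps)} components)")
        if on_disconnected == "gcc":
            logger.warning(
                "input has %d components; analysing the giant component "
                "(%d of %d nodes)", len(comps), len(comps[0]), g.n_nodes,
            )
            g = giant_component(g)
        elif on_disconnected == "components":
            return _run_components(g, comps, config)
        else:
            raise ValueError(f"unknown on_disconnected mode {on_disconnected!r}")
    levels = _run_connected(g, measure, w_threshold, epsilon, bridge_retain)
    return HAMResult(levels=levels, config=config)


def _run_components(g: Graph, comps, config) -> HAMResult:
    """Independent per-component runs, merged level-by-level (a component
    that stops early keeps contributing its final partition)."""
    per_comp = [
        _run_connected(g.subgraph(c), config["measure"], config["w_threshold"],
                       config["epsilon"], config["bridge_retain"])
        for c in comps
    ]
    depth = max(len(lv) for lv in per_comp)
    levels = []
    for lev in range(depth):
        assignment = {}
        for ci, lv in enumerate(per_comp):
            part = lv[min(lev, len(lv) - 1)][0]
            for v, c in part.assignment.items():
                assignment[v] = f"{ci}.{c}"
        part = Partition(assignment)
        levels.append((part, modularity(g, part)))
    return HAMResult(levels=levels, config=config)
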