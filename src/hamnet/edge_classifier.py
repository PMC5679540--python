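"""Classification of edges into weighted / bridge / sink sets and their
processing order.

With threshold 0 the classes are: weighted iff w > 0; among the zero-weight
edges, sink iff an endpoint has degree 1, bridge otherwise.  The
multi-resolution variant replaces 0 with a tunable ``w_threshold``: an edge
is weighted iff w > w_threshold, and the degree-1 test still decides sink
versus bridge among the remainder.

Ordering (all total and deterministic):

* weighted: weight descending, then summed endpoint degree descending, then
  lexicographic edge key ascending;
* bridge:   summed endpoint degree descending, then edge key ascending;
* sink:     same key as bridge (hub-heavy sink edges first, which lets a
  star's hub seed its community before the leaves arrive).
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import Edge, Graph
from .similarity import WeightedEdgeMap


@dataclass
class EdgeClasses:
    weighted: list[Edge]
    bridge: list[Edge]
    sink: list[Edge]
    w_threshold: float

    def __iter__(self):
        yield from self.weighted
        yield from self.bridge
        yield from self.sink


def sort_key(g: Graph, wmap: WeightedEdgeMap, edge: Edge, edge_class: str):
    """Ordering tuple for an edge within its class (smaller sorts first)."""
    i, j = edge
    ksum = g.degree(i) + g.degree(j)
    if edge_class == "weighted":
        return (-wmap[edge], -ksum, edge)
    if edge_class in ("bridge", "sink"):
        return (-ksum, edge)
    raise ValueError(f"unknown edge class {edge_class!r}")


def classify_edges(
    g: Graph, wmap: WeightedEdgeMap, w_threshold: float = 0.0
) -> EdgeClasses:
    """Partition the edges of ``g`` into weighted / bridge / sink lists.

    Raises if the threshold lies outside [0, 1].
    """
    if not 0.0 <= w_threshold <= 1.0:
        raise ValueError(f"w_threshold must be in [0, 1], got {w_threshold}")
    weighted: list[Edge] = []
    bridge: list[Edge] = []
    sink: list[Edge] = []
    for e in g.edges():
        if wmap[e] > w_threshold:
            weighted.append(e)
        elif g.degree(e[0]) == 1 or g.degree(e[1]) == 1:
            sink.append(e)
        else:
            bridge.append(e)
    weighted.sort(key=lambda e: sort_key(g, wmap, e, "weighted"))
    bridge.sort(key=lambda e: sort_key(g, wmap, e, "bridge"))
    sink.sort(key=lambda e: sort_key(g, wmap, e, "sink"))
    return EdgeClasses(weighted, bridge, sink, w_threshold)
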