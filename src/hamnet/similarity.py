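"""Topology-derived edge weights.

Every weight is computed from the two endpoint neighborhoods alone:

* ``cn``     — number of common neighbors |Γ(i) ∩ Γ(j)|
* ``cosine`` — cn / sqrt(|Γ(i)| · |Γ(j)|)
* ``jaccard``— cn / |Γ(i) ∪ Γ(j)|
* ``min``    — cn / min(|Γ(i)|, |Γ(j)|)

Γ(i) never contains i itself, so an edge's own endpoints do not count as
common neighbors; a degree-1 endpoint therefore always yields weight 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph import Edge, Graph, Node, edge_key

MEASURES = ("cn", "cosine", "jaccard", "min")


@dataclass
class WeightedEdgeMap:
    """Weights for every edge of a graph, keyed by canonical edge key."""

    weights: dict[Edge, float]
    measure: str

    def __getitem__(self, edge: Edge) -> float:
        return self.weights[edge_key(*edge)]

    def __len__(self) -> int:
        return len(self.weights)


def pair_similarity(g: Graph, i: Node, j: Node, measure: str = "min") -> float:
    """Similarity of the node pair (i, j) under the chosen measure."""
    if i == j:
        raise ValueError("similarity of a node with itself is undefined")
    if not g.has_node(i) or not g.has_node(j):
        raise KeyError(f"node {i!r} or {j!r} not in graph")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    gi, gj = g.neighbors(i), g.neighbors(j)
    cn = len(gi & gj)
    if measure == "cn":
        return float(cn)
    if cn == 0:
        return 0.0
    if measure == "cosine":
        return cn / math.sqrt(len(gi) * len(gj))
    if measure == "jaccard":
        return cn / len(gi | gj)
    return cn / min(len(gi), len(gj))


def weight_edges(g: Graph, measure: str = "min") -> WeightedEdgeMap:
    """Compute one weight per edge of ``g``; deterministic."""
    weights = {e: pair_similarity(g, e[0], e[1], measure) for e in g.edges()}
    return WeightedEdgeMap(weights=weights, measure=measure)
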