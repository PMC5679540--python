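"""Partition quality metrics: modularity Q and normalized mutual information.

Modularity compares the fraction of internal edges of each community with
the expectation under a degree-preserving random null model:

    Q = sum_i [ l_i/|E| - (d_i / 2|E|)^2 ]

with l_i the internal edge count and d_i the summed degree of community i.

NMI is the Danon form, -2 * I(A;B) / (H(A) + H(B)) computed from the
confusion matrix of shared node counts, using natural logarithms (the value
is base-invariant).  Conventions for degenerate inputs: 0·log 0 = 0; two
single-community partitions are identical (NMI 1); if exactly one partition
is trivial the score is 0.
"""

from __future__ import annotations

import math

from .graph import Graph, Partition


def modularity(g: Graph, p: Partition) -> float:
    """Newman modularity of partition ``p`` on the unweighted graph ``g``."""
    if p.nodes != g.nodes:
        missing = g.nodes ^ p.nodes
        raise ValueError(f"partition and graph node sets differ on {sorted(missing)[:5]}")
    m = g.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    internal: dict[str, int] = {}
    degree_sum: dict[str, int] = {}
    for v in g.nodes:
        c = p.assignment[v]
        degree_sum[c] = degree_sum.get(c, 0) + g.degree(v)
    for i, j in g.edges():
        ci, cj = p.assignment[i], p.assignment[j]
        if ci == cj:
            internal[ci] = internal.get(ci, 0) + 1
    q = 0.0
    for c, d in degree_sum.items():
        q += internal.get(c, 0) / m - (d / (2 * m)) ** 2
    return q


def confusion_matrix(a: Partition, b: Partition) -> dict[tuple[str, str], int]:
    """Shared-node counts N_ij between communities of a and b."""
    counts: dict[tuple[str, str], int] = {}
    for v, ca in a.assignment.items():
        key = (ca, b.assignment[v])
        counts[key] = counts.get(key, 0) + 1
    return counts


def nmi(a: Partition, b: Partition) -> float:
    """Normalized mutual information between two partitions of one node set."""
    if a.nodes != b.nodes:
        raise ValueError("partitions cover different node sets")
    n = len(a.assignment)
    if n == 0:
        raise ValueError("empty partitions")
    counts = confusion_matrix(a, b)
    row: dict[str, int] = {}
    col: dict[str, int] = {}
    for (ca, cb), c in counts.items():
        row[ca] = row.get(ca, 0) + c
        col[cb] = col.get(cb, 0) + c
    ha = -sum(ni * math.log(ni / n) for ni in row.values())
    hb = -sum(nj * math.log(nj / n) for nj in col.values())
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both single-community: identical
    if ha == 0.0 or hb == 0.0:
        return 0.0  # exactly one trivial partition
    num = 0.0
    for (ca, cb), nij in counts.items():
        num += nij * math.log(nij * n / (row[ca] * col[cb]))
    return 2.0 * num / (ha + hb)
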