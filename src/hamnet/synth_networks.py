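"""Deterministic generators for the resolution-limit test networks and a
seeded planted-partition benchmark.

Each generator returns ``(Graph, Partition)`` where the partition is the
planted ground truth.  Node labels are consecutive integers rendered as
strings, laid out clique-major with each clique's gateway node first, so
runs and traces are reproducible.

Construction details that matter for the printed network statistics:

* clique-ring: both ring edges of a clique attach to a SINGLE gateway node
  (one degree-(p+1) node per clique), which is what yields k_max = p + 1
  and the published mean clustering for K_5 rings.
* clique-pair: the two bridge endpoints inside each clique are DISTINCT
  nodes, so k_max equals the large clique size p rather than p + 1.
"""

from __future__ import annotations

import itertools

import numpy as np

from .graph import Graph, Partition


def _add_clique(g: Graph, labels: list[str]) -> None:
    for a, b in itertools.combinations(labels, 2):
        g.add_edge(a, b)


def clique_ring(p: int, r: int) -> tuple[Graph, Partition]:
    """A ring of r complete K_p cliques joined gateway-to-gateway by single
    edges; ground truth is one community per clique.

    |V| = p*r and |E| = r*p*(p-1)/2 + r.  Requires p >= 3 and r >= 3 (a
    shorter ring would collapse to a multi-edge).
    """
    if p < 3:
        raise ValueError(f"clique size p must be >= 3, got {p}")
    if r < 3:
        raise ValueError(f"ring length r must be >= 3, got {r}")
    g = Graph()
    comms: list[list[str]] = []
    for t in range(r):
        labels = [str(t * p + k) for k in range(p)]
        _add_clique(g, labels)
        comms.append(labels)
    for t in range(r):
        g.add_edge(comms[t][0], comms[(t + 1) % r][0])
    return g, Partition.from_communities(comms)


def clique_pair(p: int, q: int) -> tuple[Graph, Partition]:
    """Two K_p and two K_q cliques; each K_p is joined to each K_q by one
    edge (4 bridges, no K_p-K_p or K_q-K_q edge); ground truth is the four
    cliques.

    |V| = 2p + 2q and |E| = p(p-1) + q(q-1) + 4.  Requires p > q >= 3.
    """
    if q < 3:
        raise ValueError(f"small clique size q must be >= 3, got {q}")
    if p <= q:
        raise ValueError(f"need p > q, got p={p}, q={q}")
    g = Graph()
    offsets = [0, p, 2 * p, 2 * p + q]
    sizes = [p, p, q, q]
    comms = [[str(off + k) for k in range(sz)] for off, sz in zip(offsets, sizes)]
    for labels in comms:
        _add_clique(g, labels)
    # big clique b's bridge to small clique s leaves from its b-th/s-th
    # member, keeping the two endpoints inside every clique distinct
    for b in (0, 1):
        for s in (2, 3):
            g.add_edge(comms[b][s - 2], comms[s][b])
    return g, Partition.from_communities(comms)


def clique_line(p: int, m: int, s: int, t: int) -> tuple[Graph, Partition]:
    """A path of m K_p cliques joined gateway-to-gateway, with a chain of s
    star nodes (each carrying t degree-1 leaves) hanging off the last
    clique's gateway; ground truth is one community per clique plus one per
    star (hub and its leaves).
    """
    if p < 3 or m < 1 or s < 0 or t < 1:
        raise ValueError(f"invalid clique-line parameters p={p}, m={m}, s={s}, t={t}")
    g = Graph()
    comms: list[list[str]] = []
    for c in range(m):
        labels = [str(c * p + k) for k in range(p)]
        _add_clique(g, labels)
        comms.append(labels)
    for c in range(m - 1):
        g.add_edge(comms[c][0], comms[c + 1][0])
    nxt = m * p
    anchor = comms[-1][0]
    for _ in range(s):
        hub = str(nxt)
        leaves = [str(nxt + 1 + k) for k in range(t)]
        nxt += 1 + t
        g.add_edge(anchor, hub)
        for leaf in leaves:
            g.add_edge(hub, leaf)
        comms.append([hub] + leaves)
        anchor = hub
    return g, Partition.from_communities(comms)


def planted_partition(
    n: int, c: int, k_mean: float, u: float, seed: int
) -> tuple[Graph, Partition]:
    """Equal-size planted-partition benchmark: Bernoulli edges with
    within-community probability chosen so the expected within-community
    degree is (1-u)*k_mean and the expected between-community degree is
    u*k_mean.  Bit-reproducible for a fixed seed.
    """
    if n <= 0 or c <= 0 or n % c != 0:
        raise ValueError(f"community count {c} must divide node count {n}")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"mixing parameter u must be in [0, 1], got {u}")
    size = n // c
    if size < 2:
        raise ValueError("communities need at least 2 nodes")
    if u > 0 and c == 1:
        raise ValueError("u > 0 requires more than one community")
    p_in = (1.0 - u) * k_mean / (size - 1)
    p_out = u * k_mean / (n - size) if c > 1 else 0.0
    if p_in > 1.0 or p_out > 1.0:
        raise ValueError(
            f"infeasible edge probabilities (p_in={p_in:.3f}, p_out={p_out:.3f})"
        )
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(c), size)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    probs = np.where(same, p_in, p_out)
    mask = rng.random(len(iu)) < probs
    g = Graph(nodes=(str(v) for v in range(n)))
    for a, b in zip(iu[mask], ju[mask]):
        g.add_edge(str(a), str(b))
    comms = [[str(v) for v in range(k * size, (k + 1) * size)] for k in range(c)]
    return g, Partition.from_communities(comms)
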