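# hamnet

Community detection for undirected networks by **hierarchical arc-merging
(HAM)**: topology-derived edge weights, rule-based merging strategies, and
modularity-gain-driven coarsening.

Community structure — groups of nodes with dense internal and sparse
external connections — underlies modules in protein-interaction and
co-expression networks, guilds in microbial co-occurrence networks, and
factions in animal or human social networks. The standard workhorse,
modularity maximization, suffers from the *resolution limit*: small, tight
communities connected by single bridges get absorbed into larger ones
because the merge still raises the modularity score. `hamnet` implements a
deterministic two-phase algorithm that mitigates this, together with the
synthetic diagnostic networks (clique rings, clique pairs, clique lines,
planted partitions) and the quality metrics (modularity Q, normalized
mutual information) needed to verify every claim at desk scale.

## The algorithm

Edge weights come from the topology alone. For an edge (i, j) with
neighborhoods Γ(i), Γ(j), the weight is one of

* common neighbors: `S_cn = |Γ(i) ∩ Γ(j)|`
* cosine: `S_cn / sqrt(|Γ(i)| |Γ(j)|)`
* Jaccard: `S_cn / |Γ(i) ∪ Γ(j)|`
* minimum: `S_cn / min(|Γ(i)|, |Γ(j)|)` (default for small networks)

**Original-network phase.** Edges are classified as *weighted*
(w > w_threshold), *sink* (an endpoint of degree 1), or *bridge* (the
rest), then processed densest-to-loosest: weighted edges, sorted by
(weight, summed endpoint degree) descending, seed and grow communities
(strategy T1); bridge edges connect the resulting super-nodes without
merging them (T2); sink edges shrink leaves into their neighbor's
community (T3). The result is a super-node network where each super-node i
carries its member set, internal edge count l_i, and summed degree d_i,
and each super-edge carries the summed weight ŵ_ij and edge count e_ij of
the original edges it aggregates.

**Super-node phase.** Each super-edge gets the exact modularity gain of
merging its endpoints,

    ΔQ_ij = e_ij/|E| − (d_ij² − d_i² − d_j²) / (4|E|²),   d_ij = d_i + d_j,

and only super-edges with **ŵ > 0 and ΔQ > 0** are merged (T1, in ΔQ
order); all others only maintain structure (T2). Coarsening repeats while
merges exist and modularity keeps improving. The ŵ > 0 gate is what defeats
the resolution limit: two cliques joined by a single zero-similarity bridge
have ΔQ > 0 but ŵ = 0, so the score alone can never force them together.

## Worked example

A ring of 30 five-node cliques is the classic resolution-limit diagnostic:
plain modularity maximization prefers merging adjacent cliques pairwise
(Q = 0.8879) over the planted 30-clique partition (Q = 0.8758), while HAM
returns the planted partition exactly:

```console
$ hamnet generate clique-ring --p 5 --r 30 --out edges.tsv --truth truth.tsv
wrote 150 nodes / 330 edges to edges.tsv
$ hamnet detect --input edges.tsv --similarity min --output communities.tsv
30 communities, Q = 0.8758 (1 levels)
$ hamnet eval --metric nmi --partition communities.tsv --reference truth.tsv
1.0000
$ hamnet stats --input edges.tsv
|V|=150  |E|=330  <Cc>=0.8800  <k>=4.4000  k_max=6  r=0.0833
```

NMI = 1.0000 means the detected and planted partitions are identical; the
`stats` line shows the network's giant-component statistics (mean
clustering, mean/max degree, degree assortativity).

The same machinery is available as a scikit-learn estimator on a
precomputed adjacency matrix:

```python
from hamnet import HAMClustering, clique_ring
import numpy as np

g, truth = clique_ring(5, 30)
X = np.zeros((150, 150))
for i, j in g.edges():
    X[int(i), int(j)] = X[int(j), int(i)] = 1
est = HAMClustering(similarity="min").fit(X)
est.n_communities_, round(est.modularity_, 4)   # (30, 0.8758)
```

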