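# Methods

## Model and procedure

`hamnet` detects non-overlapping communities in undirected simple graphs.
It assumes nothing about the degree distribution, but its premise is
structural: edges *inside* a community tend to close triangles (their
endpoints share neighbors), while edges *between* communities tend not to.
That premise is encoded twice — once as the similarity weight that drives
the first merging sweep, and once as the ŵ > 0 gate that protects small
communities from modularity's resolution limit.

The procedure is deterministic end to end:

1. **Weighting.** Every edge gets a similarity weight from its endpoint
   neighborhoods (`cn`, `cosine`, `jaccard`, or `min`). Γ(i) never contains
   i itself, so the edge's own endpoints are not common neighbors and any
   degree-1 endpoint forces weight 0.
2. **Classification and ordering.** Edges with w > w_threshold are
   *weighted*; among the rest, those with a degree-1 endpoint are *sink*
   and the others are *bridge*. Weighted edges are processed in
   (w desc, k_i + k_j desc, edge key asc) order — at equal weight, the
   higher-degree edge sits in a larger dense region and carries more
   community information, so it merges first. Bridge and sink edges use
   (k_i + k_j desc, edge key asc).
3. **Merging rules.** One sweep per class: T1 (weighted) creates a
   super-node from an edge with two unmerged endpoints and absorbs a free
   endpoint into an existing super-node; T2 (bridge) *retains* two unmerged
   endpoints as separate super-nodes connected by a super-edge, and absorbs
   a free endpoint next to an existing community; T3 (sink) merges every
   leaf into its neighbor's super-node. Whenever both endpoints are already
   merged, the edge is only bookkept: an internal-edge count if they share
   a super-node, otherwise an accumulated super-edge (summed weight ŵ,
   original-edge count e).
4. **Coarsening.** On the super-node graph, every super-edge gets the exact
   modularity gain ΔQ of merging its endpoints, computed from the
   level-entry internal edge counts and summed degrees. Super-edges with
   ŵ > 0 and ΔQ > 0 are merged by T1 in (ΔQ desc, ŵ desc) order; the rest
   maintain structure via T2. Levels repeat while merge candidates exist,
   merges actually happen, and modularity improves by more than `epsilon`.

Modularity is always evaluated on the original unweighted graph (|E| is
the original edge count); ŵ is used only for gating and ordering. This
matches the analytic modularity of the benchmark partitions and keeps Q
comparable across levels.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `similarity` | `min` | weight measure; `min` is the sharpest separator on small dense networks, `cosine` scales better to large sparse ones |
| `w_threshold` | 0.0 | multi-resolution knob in [0, 1]; an edge is "weighted" only if w strictly exceeds it. Raising it moves low-similarity edges into the bridge class, splitting communities more finely |
| `epsilon` | 0.0 | minimum modularity gain to accept a coarsening level; 0 accepts any strict improvement |
| `bridge_retain` | off | in T2, retain the free endpoint of a half-merged bridge edge as its own community instead of absorbing it; reduces over-merging of star chains (see limitations) at the cost of fragmenting sparse peripheries |

## Rule semantics as a design reading

The five merge rules admit a parenthetical alternative ("or retain the
free endpoint as its own super-node"). This package fixes one reading:
absorption is the default everywhere, retention happens only in T2's
both-unmerged case (R4) and, optionally, under `bridge_retain`. T3
additionally bootstraps a super-node for a still-unmerged hub before
merging its leaves (a pure absorb-only sweep needs a first super-node; a
two-leaf dyad component becomes a single super-node). ΔQ values are
computed once per level from level-entry state, not refreshed after
intra-level merges — classification and sorting happen once per level.
These choices are this package's own reconstruction of the strategy
descriptions; they are validated end to end by the benchmark partitions
and scores the test suite asserts (clique-ring Q = 0.8758 with NMI = 1,
clique-pair Q = 0.5416 with NMI = 1, karate two-faction Q = 0.3715 with
NMI = 1). Ties everywhere break on the lexicographic (min-endpoint,
max-endpoint) edge key, making runs bit-reproducible.

## Synthetic generators: what they emulate

* `clique_ring(p, r)` — r complete K_p cliques in a ring, joined
  gateway-to-gateway by single edges, with both ring edges of a clique on
  a *single* gateway node. One degree-(p+1) node per clique is what
  produces k_max = 6 and mean clustering 0.8800 for (5, 30); two distinct
  gateways would give k_max = 5 and 0.84.
* `clique_pair(p, q)` — two K_p and two K_q, each large clique joined to
  each small one by a single edge, bridge endpoints *distinct* inside
  every clique (a shared endpoint would give k_max = p + 1, not p).
  Note the degree pairing over edges of this construction is fully
  determined, and yields degree assortativity r = 0.8908 under every
  standard convention (plain or excess-degree Pearson; networkx and igraph
  agree) — our tests assert against those independent oracles.
* `clique_line(p, m, s, t)` — a path of cliques plus a chain of s stars
  with t leaves each; the structure on which absorption-default T2
  over-merges (below).
* `planted_partition(n, c, k_mean, u, seed)` — equal-size communities with
  Bernoulli edges, expected within-degree (1−u)·k_mean and between-degree
  u·k_mean. A deliberate simplification of power-law benchmark generators:
  it has no degree or community-size heterogeneity, so recovery results on
  it say nothing about hub-dominated networks. Defaults n=128, c=4,
  k_mean=16 give a well-connected graph whose communities are
  unambiguous at low mixing — the regime where a correct implementation
  must recover the planted structure (median NMI ≥ 0.95 for u ≤ 0.2
  across seeds, asserted in the tests).

Passing tests on these generators demonstrate correctness of the
machinery and resolution-limit behaviour, not performance on real data:
real networks add degree heterogeneity, overlapping groups and noise that
none of the generators model. The bundled 34-node karate network is the
only real fixture; its ground truth uses the benchmark-conventional
two-faction split (the weakly-affiliated actor 8 with the officers'
faction — the maximum-modularity 2-split, Q = 0.3715), documented in the
fixture file itself.

## Numerical choices and degenerate inputs

* NMI uses natural logarithms (base-invariant), the 0·log 0 = 0
  convention, returns 1 when both partitions are single-community and 0
  when exactly one is trivial; it agrees with scikit-learn's
  arithmetic-mean normalization to 1e-9 on random pairs.
* Degree assortativity is the Pearson correlation of degrees over the 2|E|
  directed edge ends; on degree-regular graphs the variance is zero and
  the statistic is reported as undefined (`None`), not NaN.
* Local clustering of degree-0/1 nodes counts as 0 in the mean (not
  excluded) — required to reproduce the benchmark clustering values.
* A disconnected input is analysed as its giant component with a warning
  (`on_disconnected="gcc"`), per-component (`"components"`), or rejected
  (`"error"`). Isolated nodes become singleton communities in
  per-component mode.
* Modularity requires at least one edge; ΔQ requires |E| > 0; similarity
  of a node with itself is an error rather than 1.

## Problem sizes

The test suite and the acceptance script run entirely on generated
networks of 9–150 nodes plus the 34-node karate fixture; property checks
use a few hundred random graphs of ≤ 30 nodes and exhaustive-search
baselines on ≤ 8 nodes (all set partitions, Bell(8) = 4140). These sizes
make every expected value either analytic or brute-force verifiable. The
implementation itself is pure Python over neighbor sets; it is meant for
desk-scale analysis and method study, not for million-edge graphs.

## Known limitations

* **Star-chain over-merging.** On clique-line networks, absorption-default
  T2 lets a chain of star communities be swallowed one R3 merge at a time
  by the adjacent large community; `bridge_retain` is the built-in
  mitigation, at the cost of fragmenting sparse peripheries. This is a
  faithful property of the strategy family, not a bug.
* ΔQ is not refreshed within a level, so a level can make a merge whose
  gain would have changed sign mid-sweep; on all benchmark networks the
  final partitions are unaffected, but on larger graphs a refreshed
  variant could differ.
* The multi-resolution sweep reports one deterministic run per threshold;
  it does not search for an optimal threshold.
* Overlapping communities, weighted input edges, and node-merging variants
  are out of scope.
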