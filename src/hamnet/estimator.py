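"""scikit-learn style estimator wrapping the arc-merging detector.

The estimator consumes a square (dense or sparse) adjacency matrix, the
same convention as ``sklearn.cluster.SpectralClustering`` with a
precomputed affinity: any nonzero off-diagonal entry is an edge.  Input
values are treated as unweighted structure — all edge weights used by the
algorithm are recomputed from topology.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .graph import Graph
from .supernode_phase import run_ham


class HAMClustering(ClusterMixin, BaseEstimator):
    """Community detection on an adjacency matrix by hierarchical
    arc-merging.

    Parameters
    ----------
    similarity : {"cn", "cosine", "jaccard", "min"}, default="min"
        Topological similarity used as the edge weight.
    weight_threshold : float, default=0.0
        Multi-resolution threshold; an edge is "weighted" when its
        similarity strictly exceeds it.
    epsilon : float, default=0.0
        Minimum modularity gain required to accept a further coarsening
        level.
    bridge_retain : bool, default=False
        If True the structure-maintenance sweep retains the free endpoint
        of a half-merged bridge edge as its own super-node instead of
        absorbing it.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Community index of each node, 0..n_communities_-1.
    modularity_ : float
        Modularity of the final partition on the input graph.
    n_communities_ : int
    n_levels_ : int
        Number of accepted hierarchy levels.
    """

    def __init__(
        self,
        similarity: str = "min",
        weight_threshold: float = 0.0,
        epsilon: float = 0.0,
        bridge_retain: bool = False,
    ):
        self.similarity = similarity
        self.weight_threshold = weight_threshold
        self.epsilon = epsilon
        self.bridge_retain = bridge_retain

    def fit(self, X, y=None):
        """Detect communities in the graph whose adjacency matrix is X."""
        X = check_array(X, accept_sparse=["csr", "csc", "coo"])
        n, m = X.shape
        if n != m:
            raise ValueError(f"adjacency matrix must be square, got {X.shape}")
        if sparse.issparse(X):
            coo = sparse.coo_matrix(X)
            pairs = zip(coo.row.tolist(), coo.col.tolist())
            ij = [(a, b) for a, b in pairs if a < b]
        else:
            a, b = np.nonzero(X)
            ij = [(int(r), int(c)) for r, c in zip(a, b) if r < c]
        g = Graph(nodes=(str(v) for v in range(n)))
        for r, c in ij:
            g.add_edge(str(r), str(c))
        result = run_ham(
            g,
            measure=self.similarity,
            w_threshold=self.weight_threshold,
            epsilon=self.epsilon,
            bridge_retain=self.bridge_retain,
            on_disconnected="components",
        )
        part = result.final_partition
        order = sorted(part.communities.items(), key=lambda kv: min(int(v) for v in kv[1]))
        labels = np.empty(n, dtype=np.int64)
        for idx, (_, members) in enumerate(order):
            for v in members:
                labels[int(v)] = idx
        self.labels_ = labels
        self.modularity_ = result.final_q
        self.n_communities_ = len(order)
        self.n_levels_ = result.n_levels
        self.n_features_in_ = n
        return self
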