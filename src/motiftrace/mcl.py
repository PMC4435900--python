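"""Markov Cluster Algorithm over the one-to-one orthology graph.

MCL simulates random-walk flow on the graph: the column-stochastic
transition matrix is alternately *expanded* (matrix power, spreading flow)
and *inflated* (entrywise power followed by column renormalisation,
sharpening flow) until the flow stabilises.  Dense regions of the graph trap
flow and emerge as clusters — here, protein families/subfamilies.  The
inflation exponent controls granularity: larger values give more, smaller
clusters.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["MarkovClustering", "mcl_cluster"]


class MarkovClustering(BaseEstimator, ClusterMixin):
    """MCL graph clustering as an sklearn-style estimator.

    Parameters
    ----------
    inflation : float, default 2.0
        Entrywise power applied at each inflation step; must be > 1.
    expansion : int, default 2
        Matrix power applied at each expansion step; must be >= 2.
    self_loops : float, default 1.0
        Weight of the self-loop added to every node before normalisation
        (damps bipartite-style oscillation).
    prune_below : float, default 1e-8
        Entries below this value are zeroed (then columns renormalised).
    max_iter : int, default 200
    tol : float, default 1e-8
        Convergence when the max absolute entry change falls below ``tol``.

    Attributes
    ----------
    labels_ : ndarray of int, cluster id per node (input order).
    n_clusters_ : int
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, inflation: float = 2.0, expansion: int = 2,
                 self_loops: float = 1.0, prune_below: float = 1e-8,
                 max_iter: int = 200, tol: float = 1e-8):
        self.inflation = inflation
        self.expansion = expansion
        self.self_loops = self_loops
        self.prune_below = prune_below
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if int(self.expansion) < 2:
            raise ValueError("expansion must be an integer >= 2")

    @staticmethod
    def _normalize(m: np.ndarray) -> np.ndarray:
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        return m / colsum

    def fit(self, X, y=None) -> "MarkovClustering":
        """Cluster an adjacency matrix (dense/sparse square array) or a
        networkx graph."""
        self._validate()
        if isinstance(X, nx.Graph):
            nodes = sorted(X.nodes())
            adj = nx.to_numpy_array(X, nodelist=nodes)
            self.node_order_ = nodes
        else:
            adj = np.asarray(
                X.todense() if hasattr(X, "todense") else X, dtype=float)
            self.node_order_ = list(range(adj.shape[0]))
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if adj.shape[0] == 0:
            raise ValueError("graph is empty")
        if np.any(adj < 0):
            raise ValueError("edge weights must be >= 0")

        m = adj + self.self_loops * np.eye(adj.shape[0])
        m = self._normalize(m)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            prev = m
            m = np.linalg.matrix_power(m, int(self.expansion))   # expand
            m = self._normalize(np.power(m, self.inflation))     # inflate
            m[m < self.prune_below] = 0.0                        # prune
            m = self._normalize(m)
            err = np.abs(m.sum(axis=0) - 1.0).max()
            if err > 1e-9:  # pragma: no cover - guarded by construction
                raise AssertionError("column stochasticity lost")
            if np.abs(m - prev).max() < self.tol:
                converged = True
                break
        self.converged_ = converged
        self.n_iter_ = it
        self.matrix_ = m
        self.labels_ = self._extract_clusters(m)
        self.n_clusters_ = int(self.labels_.max()) + 1
        return self

    def _extract_clusters(self, m: np.ndarray) -> np.ndarray:
        """Clusters from the attractor structure of the converged matrix.

        Attractors are nodes with positive return flow (m[i, i] > 0); each
        node joins the attractor receiving its largest flow (lexicographic
        tie-break), and attractor sets overlapping through shared nodes are
        merged via connected components.
        """
        n = m.shape[0]
        eps = max(self.prune_below, 1e-12)
        attractors = np.flatnonzero(np.diag(m) > eps)
        if len(attractors) == 0:
            attractors = np.array([int(np.argmax(m[:, j]))
                                   for j in range(n)])
            attractors = np.unique(attractors)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for j in range(n):
            flows = m[attractors, j]
            if flows.max() <= eps and j not in set(attractors):
                continue  # stray node: becomes a singleton
            g.add_edge(j, int(attractors[int(np.argmax(flows))]))
        labels = np.full(n, -1, dtype=int)
        comps = sorted(nx.connected_components(g), key=min)
        for cid, comp in enumerate(comps):
            for v in comp:
                labels[v] = cid
        return labels

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def mcl_cluster(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
                self_loops: float = 1.0, prune_below: float = 1e-8,
                max_iter: int = 200, tol: float = 1e-8
                ) -> tuple[dict, bool]:
    """Cluster a networkx graph; returns (node -> cluster id, converged)."""
    est = MarkovClustering(inflation=inflation, expansion=expansion,
                           self_loops=self_loops, prune_below=prune_below,
                           max_iter=max_iter, tol=tol).fit(graph)
    mapping = {node: int(cid)
               for node, cid in zip(est.node_order_, est.labels_)}
    return mapping, est.converged_
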