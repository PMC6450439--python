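"""Interaction-network construction and Markov clustering (MCL).

Edges come from a user-supplied combined-score list (0–1 scale).  Only
edges with score >= 0.7 (inclusive) between genes of interest — typically
the significant genes of a contrast — are retained.  Clusters are found
with the Markov Cluster algorithm: build a column-stochastic transition
matrix with self-loops (weighted by each node's maximum incident edge
weight), then alternate expansion (matrix squaring) and inflation
(entry-wise power followed by column renormalization) until the matrix
stops changing; clusters are the connected components of the limit
matrix's support.  The default inflation of 1.5 yields coarse clusters.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import EdgeList, ValidationError

__all__ = [
    "filter_edges",
    "MarkovClustering",
    "mcl",
]

logger = logging.getLogger(__name__)


def filter_edges(
    edge_list: EdgeList,
    threshold: float = 0.7,
    gene_universe: set[str] | None = None,
) -> EdgeList:
    """Keep edges with score >= threshold and both endpoints in the universe."""
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    edges = edge_list.edges
    keep = edges["combined_score"] >= threshold
    if gene_universe is not None:
        keep &= edges["gene_a"].isin(gene_universe) & edges["gene_b"].isin(gene_universe)
    return EdgeList(edges[keep].reset_index(drop=True))


class MarkovClustering(BaseEstimator):
    """MCL graph clustering.

    Parameters
    ----------
    inflation : float, default 1.5
        Entry-wise power applied between expansions; larger values give
        finer clusters.
    max_iter : int, default 200
    tol : float, default 1e-6
        Convergence on the maximum absolute entry change per iteration.
    prune : float, default 1e-8
        Entries below this are zeroed (per column) after inflation.

    Attributes
    ----------
    clusters_ : list of node sets (a partition; singletons allowed)
    labels_ : dict node -> cluster id
    n_iter_ : iterations run
    converged_ : bool
    """

    def __init__(
        self,
        inflation: float = 1.5,
        max_iter: int = 200,
        tol: float = 1e-6,
        prune: float = 1e-8,
    ):
        self.inflation = inflation
        self.max_iter = max_iter
        self.tol = tol
        self.prune = prune

    def fit(self, edge_list: EdgeList) -> "MarkovClustering":
        if len(edge_list) == 0:
            raise ValidationError("cannot cluster an empty edge list")
        nodes = sorted(edge_list.genes)
        index = {g: i for i, g in enumerate(nodes)}
        n = len(nodes)

        adj = np.zeros((n, n))
        for a, b, w in edge_list.edges.itertuples(index=False):
            adj[index[a], index[b]] = w
            adj[index[b], index[a]] = w
        # self-loops: each node's maximum incident weight
        np.fill_diagonal(adj, adj.max(axis=1))

        m = adj / adj.sum(axis=0, keepdims=True)
        converged = False
        iteration = 0
        for iteration in range(1, self.max_iter + 1):
            expanded = m @ m
            inflated = expanded**self.inflation
            inflated[inflated < self.prune] = 0.0
            colsums = inflated.sum(axis=0, keepdims=True)
            colsums[colsums == 0] = 1.0
            inflated /= colsums
            change = np.abs(inflated - m).max()
            m = inflated
            if change < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("MCL did not converge in %d iterations", self.max_iter)

        support = nx.from_numpy_array((m + m.T) > self.prune)
        components = [
            sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)
        ]
        components.sort(key=lambda c: (-len(c), c[0]))
        self.clusters_ = [set(c) for c in components]
        self.labels_ = {g: cid for cid, comp in enumerate(components) for g in comp}
        self.n_iter_ = iteration
        self.converged_ = converged
        return self

    def fit_predict(self, edge_list: EdgeList) -> dict[str, int]:
        return self.fit(edge_list).labels_


def mcl(
    edge_list: EdgeList,
    inflation: float = 1.5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[set[str]]:
    """Functional wrapper: MCL clusters of a (filtered) edge list."""
    return MarkovClustering(inflation=inflation, max_iter=max_iter, tol=tol).fit(
        edge_list
    ).clusters_
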