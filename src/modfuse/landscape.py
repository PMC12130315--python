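"""Neighborhood graph, 2-D embedding, graph distances, Leiden clusters,
and the Ward structure tree.

The fused similarity matrix is complemented to a dissimilarity and fed,
as a precomputed metric, to the standard fuzzy simplicial set
construction (k-nearest-neighbor graph with per-point bandwidth
calibration and fuzzy-union symmetrization). That weighted graph is the
"functional landscape": it is embedded in 2-D for display, clustered
with the Leiden algorithm under modularity, and converted into a
shortest-path metric with edge length ``1 - log(adjacency)`` that blends
local neighborhood structure with global connectivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

from .matrices import DistanceMatrix, FusedSimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "ClusterAssignment",
    "DendrogramTree",
    "build_graph",
    "embed",
    "graph_distances",
    "leiden_cluster",
    "ward_tree",
    "FunctionalLandscape",
    "WardTree",
]


@dataclass
class NeighborGraph:
    """Weighted undirected fuzzy neighbor graph, adjacency in (0, 1]."""

    ids: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        a.eliminate_zeros()
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.ids):
            raise ValueError("adjacency must be square and match ids")
        if abs(a - a.T).max() > 1e-9:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops not allowed")
        if a.nnz and (a.data <= 0).any() or a.nnz and a.data.max() > 1 + 1e-9:
            raise ValueError("adjacency weights must lie in (0, 1]")
        a.data = np.minimum(a.data, 1.0)
        deg = np.asarray((a > 0).sum(axis=1)).ravel()
        if (deg == 0).any():
            raise ValueError("every entity must have at least one edge")
        self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.ids)

    def edge_list(self) -> pd.DataFrame:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame({
            "source": [self.ids[i] for i in coo.row],
            "target": [self.ids[j] for j in coo.col],
            "adjacency": coo.data,
        })

    def to_igraph(self) -> ig.Graph:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        g = ig.Graph(n=self.n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                     edge_attrs={"weight": coo.data.tolist()})
        g.vs["name"] = self.ids
        return g


@dataclass
class ClusterAssignment:
    """Entity -> cluster id, plus the modularity of the partition."""

    ids: list[str]
    labels: np.ndarray
    modularity: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.ids):
            raise ValueError("one label per entity required")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.ids, name="cluster")


@dataclass
class DendrogramTree:
    """Ward merge tree with square-root-scaled branch lengths."""

    ids: list[str]
    linkage: np.ndarray
    newick: str


def _dissimilarity_input(fused) -> tuple[list[str], np.ndarray]:
    if isinstance(fused, FusedSimilarityMatrix):
        d = fused.dissimilarity()
        ids = fused.ids
    elif isinstance(fused, DistanceMatrix):
        d, ids = fused.values, fused.ids
    else:
        d = np.asarray(fused, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    if np.isnan(d).any():
        raise ValueError("landscape input must be a complete dissimilarity matrix")
    return list(ids), d


def build_graph(fused, n_neighbors: int = 15, random_state=None) -> NeighborGraph:
    """Fuzzy k-nearest-neighbor graph from fused similarities.

    The fused dissimilarity (1 - similarity) is used as a precomputed
    metric; local neighborhood size defaults to 15. The construction
    guarantees each point's nearest neighbor enters with membership 1
    and symmetrizes memberships by fuzzy union, so weights lie in (0, 1]
    and every entity keeps at least one edge.
    """
    from umap.umap_ import fuzzy_simplicial_set

    ids, d = _dissimilarity_input(fused)
    if not n_neighbors < len(ids):
        raise ValueError("n_neighbors must be smaller than the number of entities")
    rs = check_random_state(random_state)
    graph, _, _ = fuzzy_simplicial_set(d, n_neighbors, rs, "precomputed")
    graph = sp.csr_matrix(graph)
    graph.setdiag(0)
    graph.eliminate_zeros()
    return NeighborGraph(ids, graph)


def embed(graph: NeighborGraph, n_epochs: int = 500, min_dist: float = 0.1,
          random_state=None) -> pd.DataFrame:
    """2-D layout of the neighbor graph (stochastic; seeded)."""
    from umap.umap_ import find_ab_params, simplicial_set_embedding

    rs = check_random_state(random_state)
    a, b = find_ab_params(1.0, min_dist)
    # Seeded random init rather than spectral: the spectral fallback for
    # graphs with several connected components draws unseeded randomness,
    # which would break rerun-identical artifacts. The optimizer prunes
    # small memberships in place, so hand it a copy.
    coords = simplicial_set_embedding(
        None, graph.adjacency.copy().tocoo(), 2, 1.0, a, b, 1.0, 5, n_epochs,
        "random", rs, "euclidean", {}, False, {}, False)
    if isinstance(coords, tuple):
        coords = coords[0]
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("embedding produced non-finite coordinates")
    return pd.DataFrame(coords, index=graph.ids, columns=["x", "y"])


def graph_distances(graph: NeighborGraph, log_base: float = math.e) -> DistanceMatrix:
    """Shortest-path distances with edge length ``1 - log(adjacency)``.

    An adjacency of 1 gives length 1; weaker edges are longer. Pairwise
    distance is the sum of edge lengths along the shortest path;
    unreachable pairs are infinite.
    """
    a = graph.adjacency.copy().tocoo()
    if (a.data <= 0).any():
        raise ValueError("adjacency values must be positive")
    lengths = 1.0 - np.log(a.data) / math.log(log_base)
    w = sp.csr_matrix((lengths, (a.row, a.col)), shape=a.shape)
    d = shortest_path(w, method="D", directed=False)
    return DistanceMatrix(graph.ids, np.where(np.isinf(d), np.nan, d), bounded=False)


def leiden_cluster(graph: NeighborGraph, resolution: float = 1.0,
                   iterations: int = 100, seed: int = 0) -> ClusterAssignment:
    """Leiden community detection under modularity.

    Uses the configuration-model quality function at the given
    resolution (plain modularity at resolution 1.0); deterministic for a
    fixed seed. The modularity of the returned partition is reported.
    """
    g = graph.to_igraph()
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, n_iterations=iterations, seed=int(seed))
    labels = np.asarray(part.membership)
    q = g.modularity(part.membership, weights="weight")
    return ClusterAssignment(graph.ids, labels, float(q))


def _sqrt_newick(node, ids, heights) -> str:
    h = math.sqrt(max(node.dist, 0.0))

    def rec(nd) -> str:
        hd = math.sqrt(max(nd.dist, 0.0))
        if nd.is_leaf():
            return f"{ids[nd.id]}"
        left, right = nd.get_left(), nd.get_right()
        parts = []
        for ch in (left, right):
            bl = hd - math.sqrt(max(ch.dist, 0.0))
            parts.append(f"{rec(ch)}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"

    return rec(node) + ";"


def ward_tree(distances: DistanceMatrix) -> DendrogramTree:
    """Agglomerative Ward tree with square-root-scaled branch lengths.

    Requires a complete distance matrix. Branch lengths in the Newick
    export are differences of square-rooted merge heights, preserving
    the ultrametric ordering while compressing tall merges.
    """
    if np.isnan(distances.values).any():
        raise ValueError("ward_tree requires a complete distance matrix")
    if distances.n < 2:
        raise ValueError("need at least 2 entities")
    Z = linkage(squareform(distances.values, checks=False), method="ward")
    root = to_tree(Z)
    newick = _sqrt_newick(root, distances.ids, None)
    return DendrogramTree(distances.ids, Z, newick)


class FunctionalLandscape(ClusterMixin, BaseEstimator):
    """Landscape clusterer over a precomputed fused dissimilarity.

    ``fit(X)`` with X a square fused-dissimilarity array (or a
    :class:`FusedSimilarityMatrix`) builds the fuzzy neighbor graph,
    optionally the 2-D embedding, the shortest-path distance matrix, and
    the Leiden partition.

    Attributes set by fit: ``graph_``, ``embedding_`` (DataFrame or
    None), ``labels_``, ``modularity_``, ``graph_distances_``.
    """

    def __init__(self, n_neighbors: int = 15, min_dist: float = 0.1,
                 n_epochs: int = 500, resolution: float = 1.0,
                 leiden_iterations: int = 100, compute_embedding: bool = True,
                 random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.n_epochs = n_epochs
        self.resolution = resolution
        self.leiden_iterations = leiden_iterations
        self.compute_embedding = compute_embedding
        self.random_state = random_state

    def fit(self, X, y=None):
        self.graph_ = build_graph(X, n_neighbors=self.n_neighbors,
                                  random_state=self.random_state)
        self.embedding_ = (embed(self.graph_, n_epochs=self.n_epochs,
                                 min_dist=self.min_dist,
                                 random_state=self.random_state)
                           if self.compute_embedding else None)
        assignment = leiden_cluster(self.graph_, resolution=self.resolution,
                                    iterations=self.leiden_iterations,
                                    seed=self.random_state)
        self.labels_ = assignment.labels
        self.modularity_ = assignment.modularity
        self.graph_distances_ = graph_distances(self.graph_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class WardTree(BaseEstimator):
    """Estimator facade over :func:`ward_tree`.

    Fit on a complete precomputed distance matrix; exposes ``linkage_``
    and ``newick_``.
    """

    def fit(self, X, y=None):
        dm = X if isinstance(X, DistanceMatrix) else DistanceMatrix(
            [str(i) for i in range(np.asarray(X).shape[0])], np.asarray(X, dtype=float))
        tree = ward_tree(dm)
        self.ids_ = tree.ids
        self.linkage_ = tree.linkage
        self.newick_ = tree.newick
        return self
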