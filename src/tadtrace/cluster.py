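"""Conformational clustering of chromatin traces (Louvain-Jaccard).

Each trace is represented by the flattened strict upper triangle of its
interpolated pairwise distance matrix (378 features for 28 loci), columns
are z-scored, and the traces are projected onto a few principal
components.  A k-nearest-neighbor graph is built in that space, edges are
re-weighted by the Jaccard similarity of the endpoints' neighbor sets
(which prunes spurious links between density regimes), and modularity-
optimizing Louvain community detection partitions the graph into
conformational clusters.  A t-SNE embedding is provided for display only.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .core import TraceSet, compute_distance_matrix, filter_by_min_observed
from .boundaries import MIN_LOCI_BOUNDARY

__all__ = [
    "TraceFeaturizer",
    "build_feature_matrix",
    "knn_jaccard_graph",
    "louvain_cluster",
    "ConformationClusterer",
    "cluster_composition",
    "embed_2d",
]


class TraceFeaturizer(BaseEstimator, TransformerMixin):
    """Trace -> fixed-length distance-profile feature vector.

    Missing loci are interpolated so every trace yields the full
    n(n-1)/2-long upper triangle; per-feature z-scoring equalizes the
    contribution of short- and long-range locus pairs.
    """

    def __init__(self, min_loci: int = MIN_LOCI_BOUNDARY, zscore: bool = True):
        self.min_loci = min_loci
        self.zscore = zscore

    def fit(self, trace_set: TraceSet, y=None):
        return self

    def transform(self, trace_set: TraceSet) -> np.ndarray:
        kept = filter_by_min_observed(trace_set, self.min_loci)
        if len(kept) == 0:
            raise ValueError("no traces pass the min_loci filter")
        n = kept.region.n_loci
        iu = np.triu_indices(n, k=1)
        X = np.empty((len(kept), iu[0].size))
        for r, t in enumerate(kept):
            dm = compute_distance_matrix(t, use_interpolation=True)
            X[r] = dm.values[iu]
        if self.zscore:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        return X


def build_feature_matrix(trace_set: TraceSet, **kwargs) -> tuple[np.ndarray, list[str]]:
    """Feature matrix plus the trace ids of the rows that passed filtering."""
    featurizer = TraceFeaturizer(**kwargs)
    X = featurizer.transform(trace_set)
    kept = filter_by_min_observed(trace_set, featurizer.min_loci)
    return X, [t.trace_id for t in kept]


def knn_jaccard_graph(
    features: np.ndarray, k_neighbors: int = 15, n_pcs: int | None = 10
) -> nx.Graph:
    """kNN graph with edges weighted by neighbor-set Jaccard similarity.

    Neighbor sets exclude the node itself; an undirected edge is kept for
    every directed kNN link whose endpoints share at least one neighbor
    (zero-weight edges are dropped).
    """
    X = np.asarray(features, dtype=float)
    m = X.shape[0]
    if n_pcs is not None and 0 < n_pcs < min(X.shape):
        X = PCA(n_components=n_pcs, random_state=0).fit_transform(X)
    k = min(k_neighbors, m - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = []
    for i in range(m):
        ordered = [int(j) for j in idx[i] if j != i]  # nearest first, self excluded
        neighbor_sets.append(set(ordered[:k]))
    g = nx.Graph()
    g.add_nodes_from(range(m))
    seen = set()
    for i in range(m):
        for j in neighbor_sets[i]:
            e = (i, j) if i < j else (j, i)
            if e in seen:
                continue
            seen.add(e)
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            if union and inter:
                g.add_edge(*e, weight=inter / union)
    return g


def louvain_cluster(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain community labels, sorted by descending community size.

    Deterministic for a fixed seed; ties between equal-sized communities
    are broken by their smallest member index.
    """
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for label, members in enumerate(ordered):
        for node in members:
            labels[node] = label
    return labels


class ConformationClusterer(BaseEstimator, ClusterMixin):
    """Louvain-Jaccard clustering of trace feature vectors.

    Parameters mirror the graph construction: ``k_neighbors`` nearest
    neighbors, projection onto ``n_pcs`` principal components, Louvain
    ``resolution``, and ``random_state`` for determinism.  The cluster
    count is emergent, not fixed in advance.

    Attributes (after fit): ``labels_``, ``graph_``, ``n_clusters_``.
    """

    def __init__(
        self,
        k_neighbors: int = 15,
        n_pcs: int | None = 10,
        resolution: float = 1.0,
        random_state: int = 0,
    ):
        self.k_neighbors = k_neighbors
        self.n_pcs = n_pcs
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        self.graph_ = knn_jaccard_graph(X, k_neighbors=self.k_neighbors, n_pcs=self.n_pcs)
        self.labels_ = louvain_cluster(
            self.graph_, resolution=self.resolution, seed=self.random_state
        )
        self.n_clusters_ = int(self.labels_.max()) + 1
        return self


def cluster_composition(labels: np.ndarray, groups) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster composition by group label (condition or allele).

    Returns ``(by_group, by_cluster)``: ``by_group`` gives, for each group
    value, the fraction of its traces in each cluster (rows sum to 1);
    ``by_cluster`` gives each cluster's group mixture (rows sum to 1).
    """
    df = pd.DataFrame({"cluster": np.asarray(labels), "group": list(groups)})
    counts = pd.crosstab(df["group"], df["cluster"])
    by_group = counts.div(counts.sum(axis=1), axis=0)
    counts_c = pd.crosstab(df["cluster"], df["group"])
    by_cluster = counts_c.div(counts_c.sum(axis=1), axis=0)
    return by_group, by_cluster


def embed_2d(features: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """t-SNE display embedding (no quantitative claims attach to it)."""
    X = np.asarray(features, dtype=float)
    m = X.shape[0]
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (m - 1) / 3.0))
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    )
    return tsne.fit_transform(X)
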