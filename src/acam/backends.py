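"""Self-contained clustering backends for the consensus stage.

The consensus construction only needs several partitions produced by
methods with different inductive biases; any clustering method can stand
behind a backend. The five defaults are: Leiden on a PCA kNN graph,
k-means on a 2-D t-SNE embedding, k-means on PCA, a Gaussian mixture on
PCA, and Ward agglomeration on PCA. Methods that need a cluster number
estimate it themselves with a silhouette scan.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

DEFAULT_BACKENDS = ["leiden", "tsne-kmeans", "kmeans", "gmm", "ward"]


def _pca(x: np.ndarray, seed: int, n_components: int = 30) -> np.ndarray:
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    return PCA(n_components=n_components, random_state=seed).fit_transform(x)


def _silhouette_scan(
    x: np.ndarray,
    fit_predict,
    k_range: range,
) -> np.ndarray:
    """Pick the cluster count maximizing the silhouette width."""
    best_labels, best_score = None, -np.inf
    for k in k_range:
        if k >= x.shape[0]:
            break
        labels = fit_predict(k)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if score > best_score:
            best_labels, best_score = labels, score
    if best_labels is None:  # degenerate data: everything in one cluster
        return np.zeros(x.shape[0], dtype=int)
    return np.asarray(best_labels)


def _k_range(n: int, k_max: int = 10) -> range:
    return range(2, min(k_max, n - 1) + 1)


def leiden_backend(x: np.ndarray, seed: int, n_neighbors: int = 15,
                   resolution: float = 1.0) -> np.ndarray:
    import igraph
    import leidenalg

    pcs = _pca(x, seed)
    k = min(n_neighbors, x.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {tuple(sorted((i, int(j)))) for i in range(x.shape[0]) for j in idx[i, 1:]}
    g = igraph.Graph(n=x.shape[0], edges=list(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed,
    )
    return np.asarray(part.membership)


def tsne_kmeans_backend(x: np.ndarray, seed: int) -> np.ndarray:
    n = x.shape[0]
    perplexity = max(2.0, min(30.0, (n - 1) / 3))
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(_pca(x, seed))
    return _silhouette_scan(
        emb,
        lambda k: KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(emb),
        _k_range(n),
    )


def kmeans_backend(x: np.ndarray, seed: int) -> np.ndarray:
    pcs = _pca(x, seed)
    return _silhouette_scan(
        pcs,
        lambda k: KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(pcs),
        _k_range(x.shape[0]),
    )


def gmm_backend(x: np.ndarray, seed: int) -> np.ndarray:
    pcs = _pca(x, seed)
    return _silhouette_scan(
        pcs,
        lambda k: GaussianMixture(
            n_components=k, random_state=seed, n_init=3
        ).fit_predict(pcs),
        _k_range(x.shape[0]),
    )


def ward_backend(x: np.ndarray, seed: int) -> np.ndarray:
    pcs = _pca(x, seed)
    return _silhouette_scan(
        pcs,
        lambda k: AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(pcs),
        _k_range(x.shape[0]),
    )


BACKEND_REGISTRY = {
    "leiden": leiden_backend,
    "tsne-kmeans": tsne_kmeans_backend,
    "kmeans": kmeans_backend,
    "gmm": gmm_backend,
    "ward": ward_backend,
}
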