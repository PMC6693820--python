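"""Embedding, density clustering, and cluster dendrograms.

The combined distance matrix is noisy and need not satisfy the triangle
inequality, so it is smoothed through two embedding steps before
clustering: classical (Torgerson) multidimensional scaling into a
50-dimensional Euclidean space (negative eigenvalues, the signature of
non-metric input, are clipped to zero and counted), then Barnes-Hut t-SNE
down to three dimensions. t-SNE is restarted several times and the run
with the lowest final Kullback-Leibler divergence is kept. Clusters are
extracted from the 3-D embedding with OPTICS, and summarized as an
average-linkage dendrogram over cluster-to-cluster mean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform
from sklearn.manifold import TSNE
from sklearn.cluster import OPTICS, cluster_optics_dbscan

from viratax.matrix import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    ids: list[str]
    mds_coords: np.ndarray  # (n, 50)
    tsne_coords: np.ndarray  # (n, 3)
    kl_divergence: float  # minimum over restarts
    seed: int
    n_restarts: int


@dataclass
class Clustering:
    labels: np.ndarray  # per-genome int, -1 = noise
    reachability: np.ndarray
    ordering: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if (self.labels >= 0).any() else 0


@dataclass
class Dendrogram:
    leaves: list[int]  # cluster ids
    merges: list[tuple[int, int, float]]  # (node, node, height)
    linkage: np.ndarray  # scipy linkage matrix over clusters

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]


def classical_mds(matrix: DistanceMatrix, dims: int = 50) -> tuple[np.ndarray, int]:
    """Torgerson classical MDS.

    Double-centers the squared distance matrix, eigendecomposes it, and
    builds coordinates from the positive eigenpairs; negative eigenvalues
    (non-Euclidean input) are discarded and their count returned and
    logged. Columns beyond the number of positive eigenvalues are zero.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("classical MDS needs at least 3 genomes")
    if not np.isfinite(matrix.values).all():
        raise ValueError("MDS input must be finite (combine distances first)")
    d2 = matrix.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-9 * max(abs(eigvals[0]), 1.0), 0.0)
    n_negative = int((eigvals < -tol).sum())
    if n_negative:
        logger.info("classical MDS: clipped %d negative eigenvalues "
                    "(non-metric input)", n_negative)
    positive = np.clip(eigvals, 0.0, None)
    n_pos = int((positive > tol).sum())
    keep = min(dims, n_pos)
    coords = np.zeros((n, dims))
    coords[:, :keep] = eigvecs[:, :keep] * np.sqrt(positive[:keep])
    return coords, n_negative


def tsne_embed(
    coords: np.ndarray,
    ids: list[str],
    perplexity: float = 30.0,
    theta: float = 0.5,
    n_restarts: int = 20,
    out_dims: int = 3,
    seed: int = 0,
) -> Embedding:
    """Barnes-Hut t-SNE with restarts; keeps the lowest-KL run.

    Restart r uses random state ``seed + r``, so results are reproducible
    for a fixed seed. If the sample is too small for the requested
    perplexity (n <= 3 * perplexity), perplexity is reduced to
    floor((n - 1) / 3) with a warning.
    """
    n = coords.shape[0]
    if n <= 3 * perplexity:
        new_p = max((n - 1) // 3, 1)
        logger.warning("perplexity %g too large for n=%d; reduced to %d",
                       perplexity, n, new_p)
        perplexity = float(new_p)
    best_coords, best_kl = None, np.inf
    for r in range(n_restarts):
        tsne = TSNE(
            n_components=out_dims,
            perplexity=perplexity,
            angle=theta,
            method="barnes_hut",
            init="random",
            random_state=seed + r,
            n_jobs=1,
        )
        emb = tsne.fit_transform(coords)
        if tsne.kl_divergence_ < best_kl:
            best_kl = float(tsne.kl_divergence_)
            best_coords = emb
    return Embedding(ids=list(ids), mds_coords=coords, tsne_coords=best_coords,
                     kl_divergence=best_kl, seed=seed, n_restarts=n_restarts)


def project_2d(tsne_coords: np.ndarray) -> np.ndarray:
    """2-D PCA projection of the 3-D embedding (plotting only)."""
    centered = tsne_coords - tsne_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def optics_clusters(
    coords: np.ndarray,
    min_samples: int = 5,
    method: str = "cut",
    xi: float = 0.05,
    eps: float | None = None,
) -> Clustering:
    """Density clustering of the 3-D embedding with OPTICS.

    Three ways to extract clusters from the reachability plot:

    - ``method="cut"`` (default): cut the reachability plot at a single
      threshold. With ``eps=None`` the threshold is placed in the middle of
      the largest gap in the sorted finite reachability values, the level
      at which the cluster count is most stable over a range of cuts; an
      explicit ``eps`` cuts at that reachability (a strict threshold on
      sparse data labels everything noise).
    - ``method="xi"``: steepness-based extraction with threshold ``xi``.

    Points in no cluster are labeled -1 (noise).
    """
    if method == "xi":
        model = OPTICS(min_samples=min_samples, cluster_method="xi", xi=xi)
        model.fit(coords)
        labels = model.labels_
    elif method == "cut":
        model = OPTICS(min_samples=min_samples)
        model.fit(coords)
        if eps is None:
            eps = _largest_gap_eps(model.reachability_, model.ordering_)
            logger.info("reachability cut chosen at eps=%.4g", eps)
        labels = cluster_optics_dbscan(
            reachability=model.reachability_,
            core_distances=model.core_distances_,
            ordering=model.ordering_,
            eps=eps,
        )
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    labels = _contiguous_labels(labels)
    return Clustering(
        labels=labels,
        reachability=model.reachability_,
        ordering=model.ordering_,
        params={"min_samples": min_samples, "method": method, "xi": xi, "eps": eps},
    )


def _largest_gap_eps(reachability: np.ndarray, ordering: np.ndarray) -> float:
    """Reachability threshold in the middle of the largest gap between
    sorted finite reachability values (densest stable cut)."""
    finite = np.sort(reachability[ordering][np.isfinite(reachability[ordering])])
    if finite.size < 2:
        raise ValueError("not enough finite reachability values to cut")
    gaps = np.diff(finite)
    i = int(np.argmax(gaps))
    return float(0.5 * (finite[i] + finite[i + 1]))


def _contiguous_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance; noise stays -1."""
    out = np.full_like(labels, -1)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def subcluster(coords: np.ndarray, clustering: Clustering, cluster_id: int,
               min_samples: int = 5, method: str = "cut", xi: float = 0.05,
               eps: float | None = None) -> tuple[np.ndarray, Clustering]:
    """Recursively re-cluster one cluster's members (drill-down analysis).

    Returns the member indices (into the original coordinate array) and a
    fresh Clustering of just those points.
    """
    members = np.where(clustering.labels == cluster_id)[0]
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} has no members")
    sub = optics_clusters(coords[members], min_samples=min_samples,
                          method=method, xi=xi, eps=eps)
    return members, sub


def cluster_dendrogram(coords: np.ndarray, clustering: Clustering) -> Dendrogram:
    """Average-linkage dendrogram over clusters in the 3-D embedding.

    The base distance between two clusters is the mean Euclidean distance
    over all inter-cluster point pairs; noise points are excluded. Branch
    lengths measure how much more similar a cluster is to itself than to
    the rest.
    """
    cluster_ids = sorted(int(c) for c in set(clustering.labels) if c >= 0)
    k = len(cluster_ids)
    if k < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    dist = np.zeros((k, k))
    groups = [coords[clustering.labels == c] for c in cluster_ids]
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = float(cdist(groups[i], groups[j]).mean())
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(leaves=cluster_ids, merges=merges, linkage=z)


def dendrogram_to_newick(dendrogram: Dendrogram, labels: list[str] | None = None) -> str:
    """Serialize the cluster dendrogram as a Newick string with branch lengths."""
    if labels is None:
        labels = [f"cluster{c}" for c in dendrogram.leaves]
    tree = hierarchy.to_tree(dendrogram.linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        lb = max(node.dist - left.dist, 0.0) / 2 if not left.is_leaf() else node.dist / 2
        rb = max(node.dist - right.dist, 0.0) / 2 if not right.is_leaf() else node.dist / 2
        return f"({walk(left)}:{lb:.6g},{walk(right)}:{rb:.6g})"

    return walk(tree) + ";"
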