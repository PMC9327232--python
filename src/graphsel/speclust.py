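"""Normalized spectral clustering of feature-graph node embeddings.

Pairwise node similarity uses a Gaussian kernel on the embedding
vectors, W_ij = exp(-||e_i - e_j||^2 / (2 * omega^2)) with zero
diagonal.  The symmetric normalized Laplacian
L_sym = D^{-1/2} (D - W) D^{-1/2} is eigendecomposed; the eigenvectors
of the mu smallest eigenvalues form the spectral embedding, whose
row-normalized rows are clustered by k-means into mu redundancy
sub-graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from graphsel.errors import ValidationError
from graphsel.graphbuild import FeatureGraph

logger = logging.getLogger(__name__)


@dataclass
class SpectralConfig:
    """Cluster count, Gaussian bandwidth and k-means settings.

    ``omega=None`` selects the median heuristic: the median pairwise
    Euclidean distance between node embeddings.
    """

    mu: int = 4
    omega: float | None = None
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 1:
            raise ValidationError("mu must be >= 1")
        if self.omega is not None and self.omega <= 0:
            raise ValidationError("omega must be > 0")


@dataclass
class ClusterPartition:
    """Node-to-cluster assignment and the induced sub-graphs."""

    node_ids: list[str]
    assignment: np.ndarray  # cluster index per node, 0..mu-1
    subgraphs: list[tuple[list[int], dict[tuple[int, int], float]]]
    eigenvalues: np.ndarray

    def clusters(self) -> list[list[str]]:
        """Feature ids per cluster (may contain empty clusters)."""
        out: list[list[str]] = [[] for _ in self.subgraphs]
        for idx, c in enumerate(self.assignment):
            out[c].append(self.node_ids[idx])
        return out


def gaussian_similarity(embeddings: np.ndarray, omega: float) -> np.ndarray:
    """Gaussian-kernel similarity matrix with zero diagonal."""
    if omega <= 0:
        raise ValidationError("omega must be > 0")
    emb = np.asarray(embeddings, dtype=float)
    if emb.shape[0] < 2:
        raise ValidationError("need at least 2 node vectors")
    sq = squareform(pdist(emb, metric="sqeuclidean"))
    w = np.exp(-sq / (2.0 * omega**2))
    np.fill_diagonal(w, 0.0)
    return w


def median_bandwidth(embeddings: np.ndarray) -> float:
    """Median pairwise Euclidean distance (fallback 1.0 if degenerate)."""
    d = pdist(np.asarray(embeddings, dtype=float))
    med = float(np.median(d)) if d.size else 0.0
    return med if med > 0 else 1.0


def normalized_laplacian(w: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian D^{-1/2} (D - W) D^{-1/2}.

    Zero-degree nodes get an identity row/column (a unit eigenvalue
    contribution) rather than a division by zero.
    """
    w = np.asarray(w, dtype=float)
    d = w.sum(axis=1)
    zero = d == 0
    if zero.any():
        logger.info("%d zero-degree nodes in similarity matrix", zero.sum())
    inv_sqrt = np.zeros_like(d)
    inv_sqrt[~zero] = 1.0 / np.sqrt(d[~zero])
    lap = -w * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(lap, 1.0)
    lap[zero, :] = 0.0
    lap[:, zero] = 0.0
    lap[zero, zero] = 1.0
    return lap


def spectral_cluster(w: np.ndarray, mu: int, kmeans_restarts: int = 10, seed: int = 0):
    """Cluster a similarity matrix into ``mu`` groups; returns (labels, eigenvalues)."""
    zeta = w.shape[0]
    if mu > zeta:
        raise ValidationError(f"mu={mu} exceeds number of nodes {zeta}")
    lap = normalized_laplacian(w)
    eigvals, eigvecs = eigh(lap, subset_by_index=(0, mu - 1))
    u = eigvecs
    norms = np.linalg.norm(u, axis=1)
    nz = norms > 0
    u = u.copy()
    u[nz] /= norms[nz, None]
    km = KMeans(n_clusters=mu, n_init=kmeans_restarts, random_state=seed)
    labels = km.fit_predict(u)
    return labels, eigvals


def spectral_partition(graph_star: FeatureGraph, config: SpectralConfig | None = None) -> ClusterPartition:
    """Partition the augmented graph's nodes into redundancy sub-graphs.

    The vectors clustered are the node embeddings carried by
    ``graph_star`` (the best link-prediction embeddings).  Induced edge
    sets keep only within-cluster edges.
    """
    config = config or SpectralConfig()
    emb = graph_star.embeddings
    omega = config.omega if config.omega is not None else median_bandwidth(emb)
    w = gaussian_similarity(emb, omega)
    labels, eigvals = spectral_cluster(
        w, config.mu, kmeans_restarts=config.kmeans_restarts, seed=config.seed
    )
    subgraphs = []
    for c in range(config.mu):
        nodes = [i for i in range(graph_star.n_nodes) if labels[i] == c]
        in_cluster = set(nodes)
        edges = {
            e: wgt
            for e, wgt in graph_star.edges.items()
            if e[0] in in_cluster and e[1] in in_cluster
        }
        subgraphs.append((nodes, edges))
    return ClusterPartition(
        node_ids=list(graph_star.node_ids),
        assignment=np.asarray(labels),
        subgraphs=subgraphs,
        eigenvalues=eigvals,
    )
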