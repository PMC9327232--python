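"""Construction of the initial feature graph from expression + prior edges.

Nodes are features; the initial node embedding is the feature's
expression profile across samples, L2-normalized.  An edge is admitted
when the pair has a positive prior weight or an absolute Pearson
correlation at least ``r_min``.  The raw edge weight is the mean of the
two evidence sources — absolute correlation and prior weight, a missing
source contributing 0 — passed through a per-node softmax over incident
edges and symmetrized by averaging the two directed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from graphsel.dataio import ExpressionDataset, PriorNetwork
from graphsel.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Signed Pearson correlations between features (diagonal 1)."""

    feature_ids: list[str]
    r: np.ndarray


@dataclass
class FeatureGraph:
    """Weighted feature graph with per-node embeddings.

    ``edges`` maps index pairs ``(i, j)`` with ``i < j`` to weights in
    (0, 1].  ``embeddings`` is an (n_nodes, d) array; ``layer`` counts
    propagation steps applied so far.
    """

    node_ids: list[str]
    edges: dict[tuple[int, int], float]
    embeddings: np.ndarray
    layer: int = 0

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if self.embeddings.shape[0] != len(self.node_ids):
            raise ValidationError("one embedding per node required")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> list[list[tuple[int, float]]]:
        """Adjacency lists of (neighbor index, edge weight)."""
        adj: list[list[tuple[int, float]]] = [[] for _ in self.node_ids]
        for (i, j), w in self.edges.items():
            adj[i].append((j, w))
            adj[j].append((i, w))
        return adj

    def copy(self) -> "FeatureGraph":
        return FeatureGraph(
            node_ids=list(self.node_ids),
            edges=dict(self.edges),
            embeddings=self.embeddings.copy(),
            layer=self.layer,
        )


def pearson_matrix(ds: ExpressionDataset) -> CorrelationMatrix:
    """Pearson correlation between every feature pair across samples.

    Constant features get r = 0 off-diagonal (their correlation is
    undefined) and 1 on the diagonal.
    """
    if ds.n_samples < 3:
        raise ValidationError("need at least 3 samples for stable correlations")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(ds.values, rowvar=False)
    r = np.atleast_2d(r)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(feature_ids=list(ds.feature_ids), r=r)


def fuse_and_normalize_edges(
    corr: CorrelationMatrix, prior: PriorNetwork, r_min: float = 0.7
) -> dict[tuple[int, int], float]:
    """Fuse correlation and prior evidence into normalized edge weights.

    Candidate pairs are those with a positive prior weight or |r| >=
    ``r_min``.  Raw weight = (|r| + prior)/2.  Each node's incident raw
    weights go through a softmax (so they sum to 1 per node), and the
    edge weight is the mean of the two directed softmax values.
    """
    ids = corr.feature_ids
    index = {f: i for i, f in enumerate(ids)}
    n = len(ids)
    candidates: set[tuple[int, int]] = set()
    abs_r = np.abs(corr.r)
    hi = np.argwhere(np.triu(abs_r >= r_min, k=1))
    candidates.update((int(i), int(j)) for i, j in hi)
    for (a, b), w in prior.weights.items():
        if w > 0 and a in index and b in index:
            i, j = index[a], index[b]
            candidates.add((i, j) if i < j else (j, i))
    raw = {(i, j): (abs_r[i, j] + prior.get(ids[i], ids[j])) / 2.0 for i, j in candidates}
    # per-node softmax over incident raw weights
    incident: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, j in raw:
        incident[i].append((i, j))
        incident[j].append((i, j))
    directed: dict[tuple[int, tuple[int, int]], float] = {}
    for v in range(n):
        if not incident[v]:
            continue
        w = np.array([raw[e] for e in incident[v]])
        w = np.exp(w - w.max())
        w /= w.sum()
        for e, s in zip(incident[v], w):
            directed[(v, e)] = float(s)
    return {
        (i, j): (directed[(i, (i, j))] + directed[(j, (i, j))]) / 2.0 for i, j in raw
    }


def build_graph(
    ds: ExpressionDataset, prior: PriorNetwork, r_min: float = 0.7
) -> FeatureGraph:
    """Build the feature graph G = {V, E} with initial embeddings h^0.

    ``ds`` is expected to be prefiltered (typically to 100 features).
    h^0 of a node is its expression profile over the samples,
    L2-normalized so the unit-norm invariant holds from layer 0.
    """
    corr = pearson_matrix(ds)
    edges = fuse_and_normalize_edges(corr, prior, r_min=r_min)
    if not edges:
        logger.warning("feature graph has no edges")
    h0 = ds.values.T.astype(float).copy()  # (n_features, n_samples)
    norms = np.linalg.norm(h0, axis=1, keepdims=True)
    nonzero = norms[:, 0] > 0
    h0[nonzero] /= norms[nonzero]
    return FeatureGraph(node_ids=list(ds.feature_ids), edges=edges, embeddings=h0, layer=0)
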