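"""Link prediction on the feature graph.

A fraction of edges is held out as positives and non-edges are sampled
as negatives.  Node embeddings (initialized from the propagation output)
are the trainable parameters; they are fitted by gradient descent on a
negative-sampling loss — ``-log sigmoid(sim)`` for held-out edges and
``-log sigmoid(-sim)`` for sampled non-edges, with cosine similarity as
the scorer.  After each epoch the mean reciprocal rank (MRR) of the
positives among their negatives is computed and the best-MRR snapshot is
kept.  The best embeddings score all remaining non-edges; the top
fraction is added to the graph, and the held-out edges restored, giving
the augmented graph G*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from graphsel.errors import NegativeSamplingError, ValidationError
from graphsel.graphbuild import FeatureGraph
from graphsel.propagate import PropagationResult

logger = logging.getLogger(__name__)


@dataclass
class EdgeSampleSet:
    """Held-out positive edges and per-positive negative non-edges."""

    pos: list[tuple[int, int]]
    neg: list[list[tuple[int, int]]]  # one group of negatives per positive
    neg_per_pos: int
    seed: int
    pos_weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def all_neg(self) -> list[tuple[int, int]]:
        return [e for group in self.neg for e in group]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    stop_epsilon: float = 1e-4
    max_epochs: int = 200


@dataclass
class LinkPredModel:
    """Trained embeddings with loss/MRR traces and the best snapshot."""

    z: np.ndarray
    best_z: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    mrr_trace: list[float] = field(default_factory=list)
    config: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class AugmentedGraph(FeatureGraph):
    """Feature graph plus the predicted edges that were added."""

    added_edges: list[tuple[int, int, float]] = field(default_factory=list)


def sample_pos_neg(
    graph: FeatureGraph,
    holdout_frac: float = 0.1,
    neg_per_pos: int = 5,
    seed: int = 0,
) -> tuple[FeatureGraph, EdgeSampleSet]:
    """Hold out edges as positives and sample non-edges as negatives.

    ``ceil(holdout_frac * |E|)`` edges are removed uniformly from the
    graph (never all of them); ``neg_per_pos`` non-adjacent pairs are
    drawn per positive, without replacement overall.

    Raises
    ------
    NegativeSamplingError
        If the graph has too few non-edges to supply the negatives.
    """
    edges = sorted(graph.edges)
    m = len(edges)
    if m < 2:
        raise ValidationError("graph needs at least 2 edges for link prediction")
    n_pos = max(1, math.ceil(holdout_frac * m))
    if n_pos >= m:
        raise ValidationError("holdout would empty the edge set")
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(m, size=n_pos, replace=False)
    pos = [edges[i] for i in sorted(pos_idx)]
    reduced = graph.copy()
    for e in pos:
        del reduced.edges[e]

    n = graph.n_nodes
    all_pairs = n * (n - 1) // 2
    non_edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in graph.edges
    ]
    needed = n_pos * neg_per_pos
    if len(non_edges) < needed:
        raise NegativeSamplingError(requested=needed, available=len(non_edges))
    neg_idx = rng.choice(len(non_edges), size=needed, replace=False)
    flat = [non_edges[i] for i in neg_idx]
    neg = [flat[k * neg_per_pos : (k + 1) * neg_per_pos] for k in range(n_pos)]
    logger.info(
        "link-pred sampling: %d/%d edges held out, %d negatives (%d pairs total)",
        n_pos, m, needed, all_pairs,
    )
    return reduced, EdgeSampleSet(
        pos=pos,
        neg=neg,
        neg_per_pos=neg_per_pos,
        seed=seed,
        pos_weights={e: graph.edges[e] for e in pos},
    )


def cosine_similarity(zi: np.ndarray, zj: np.ndarray) -> float:
    """Cosine of the angle between two embedding vectors."""
    ni, nj = np.linalg.norm(zi), np.linalg.norm(zj)
    if ni == 0 or nj == 0:
        raise ValidationError("cosine similarity undefined for zero vector")
    return float(zi @ zj / (ni * nj))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lp_loss(z: np.ndarray, sample: EdgeSampleSet) -> float:
    """Mean negative-sampling loss over the held-out positives.

    For each positive (i, j) with negatives group B:
    ``-log sigmoid(sim(i, j)) - sum_{(a,b) in B} log sigmoid(-sim(a, b))``.
    """
    total = 0.0
    for (i, j), group in zip(sample.pos, sample.neg):
        total += -np.log(_sigmoid(cosine_similarity(z[i], z[j])))
        for a, b in group:
            total += -np.log(_sigmoid(-cosine_similarity(z[a], z[b])))
    return float(total / len(sample.pos))


def lp_loss_grad(z: np.ndarray, sample: EdgeSampleSet) -> np.ndarray:
    """Analytic gradient of :func:`lp_loss` with respect to ``z``."""
    grad = np.zeros_like(z)
    n_pos = len(sample.pos)

    def accumulate(i: int, j: int, dl_ds: float) -> None:
        zi, zj = z[i], z[j]
        ni, nj = np.linalg.norm(zi), np.linalg.norm(zj)
        s = zi @ zj / (ni * nj)
        grad[i] += dl_ds * (zj / (ni * nj) - s * zi / ni**2)
        grad[j] += dl_ds * (zi / (ni * nj) - s * zj / nj**2)

    for (i, j), group in zip(sample.pos, sample.neg):
        s = cosine_similarity(z[i], z[j])
        accumulate(i, j, (_sigmoid(s) - 1.0) / n_pos)
        for a, b in group:
            s = cosine_similarity(z[a], z[b])
            accumulate(a, b, _sigmoid(s) / n_pos)
    return grad


def positive_ranks(z: np.ndarray, sample: EdgeSampleSet) -> list[float]:
    """Rank of each positive's score among its own negatives.

    Rank 1 is best; a negative scoring strictly higher adds 1, a tie
    adds 1/2 (mean-rank tie-break).
    """
    ranks = []
    for (i, j), group in zip(sample.pos, sample.neg):
        s = cosine_similarity(z[i], z[j])
        neg_scores = [cosine_similarity(z[a], z[b]) for a, b in group]
        higher = sum(1 for t in neg_scores if t > s)
        ties = sum(1 for t in neg_scores if t == s)
        ranks.append(1.0 + higher + ties / 2.0)
    return ranks


def mrr(per_positive_ranks) -> float:
    """Mean reciprocal rank: (1/n) * sum(1/rank)."""
    ranks = list(per_positive_ranks)
    if not ranks:
        raise ValidationError("MRR of an empty rank list is undefined")
    if any(r < 1 for r in ranks):
        raise ValidationError("ranks must be >= 1")
    return float(np.mean([1.0 / r for r in ranks]))


def train_link_predictor(
    prop_result: PropagationResult | FeatureGraph,
    sample: EdgeSampleSet,
    config: TrainConfig | None = None,
) -> LinkPredModel:
    """Fit node embeddings by gradient descent on the sampling loss.

    Embeddings start from the propagation output, are renormalized to
    unit norm after every epoch, and training stops when the loss change
    drops below ``stop_epsilon`` or at the epoch cap.  The snapshot with
    the highest MRR on the held-out sample is kept as ``best_z``.
    """
    config = config or TrainConfig()
    graph = prop_result.graph if isinstance(prop_result, PropagationResult) else prop_result
    z = graph.embeddings.copy()
    loss_trace: list[float] = []
    mrr_trace: list[float] = []
    best_z = z.copy()
    best_mrr = -np.inf
    for epoch in range(config.max_epochs):
        loss = lp_loss(z, sample)
        if not np.isfinite(loss):
            raise ValidationError(f"link-prediction loss diverged at epoch {epoch}")
        grad = lp_loss_grad(z, sample)
        z = z - config.learning_rate * grad
        norms = np.linalg.norm(z, axis=1)
        norms[norms == 0] = 1.0
        z /= norms[:, None]
        loss_trace.append(loss)
        m = mrr(positive_ranks(z, sample))
        mrr_trace.append(m)
        if m > best_mrr:
            best_mrr = m
            best_z = z.copy()
        if len(loss_trace) >= 2 and abs(loss_trace[-1] - loss_trace[-2]) < config.stop_epsilon:
            break
    logger.info(
        "link predictor trained for %d epochs; best MRR %.4f", len(loss_trace), best_mrr
    )
    return LinkPredModel(
        z=z, best_z=best_z, loss_trace=loss_trace, mrr_trace=mrr_trace, config=config
    )


def augment_graph(
    graph: FeatureGraph,
    model: LinkPredModel,
    sample: EdgeSampleSet | None = None,
    add_frac: float = 0.1,
) -> AugmentedGraph:
    """Add the top-scoring predicted links, giving the augmented graph G*.

    All non-edges of ``graph`` (excluding held-out positives, which are
    restored with their original weights afterwards) are scored by
    cosine similarity under ``best_z``; the top ``ceil(add_frac * |E|)``
    become new edges with weight ``max(similarity, 1e-6)``.
    """
    z = model.best_z
    held_out = {e for e in sample.pos} if sample is not None else set()
    n = graph.n_nodes
    scored = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in graph.edges or (i, j) in held_out:
                continue
            scored.append((cosine_similarity(z[i], z[j]), i, j))
    k = math.ceil(add_frac * graph.n_edges())
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    added = [(i, j, max(s, 1e-6)) for s, i, j in scored[:k]]
    edges = dict(graph.edges)
    for i, j, w in added:
        edges[(i, j)] = w
    if sample is not None:
        # restore held-out positives at their original weights
        for e in sample.pos:
            edges[e] = sample.pos_weights.get(e) or max(cosine_similarity(z[e[0]], z[e[1]]), 1e-6)
    return AugmentedGraph(
        node_ids=list(graph.node_ids),
        edges=edges,
        embeddings=z.copy(),
        layer=graph.layer,
        added_edges=added,
    )
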