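"""Parameter-free message propagation and aggregation on the feature graph.

Each step computes, synchronously for every node, a neighborhood
aggregate (edge-weighted mean of neighbor embeddings), splices it to the
node's previous embedding, applies an elementwise nonlinearity, restores
the original dimension by averaging the two halves, and renormalizes to
unit L2 norm.  Steps repeat until the largest per-node change drops
below a threshold.

There are no learnable weights; the concatenate-and-halve update keeps
self and neighbor information at constant dimension so the layer-to-layer
stopping rule stays well-posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from graphsel.errors import ValidationError
from graphsel.graphbuild import FeatureGraph

logger = logging.getLogger(__name__)

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "tanh": np.tanh,
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass
class PropagationConfig:
    """Convergence threshold, nonlinearity and layer cap for propagation."""

    epsilon: float = 0.01
    activation: str | Callable[[np.ndarray], np.ndarray] = "tanh"
    max_layers: int = 50

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.max_layers < 1:
            raise ValidationError("max_layers must be >= 1")

    def sigma(self) -> Callable[[np.ndarray], np.ndarray]:
        if callable(self.activation):
            return self.activation
        try:
            return _ACTIVATIONS[self.activation]
        except KeyError as exc:
            raise ValidationError(f"unknown activation {self.activation!r}") from exc


@dataclass
class PropagationResult:
    """Final graph state plus the number of layers and convergence trace."""

    graph: FeatureGraph
    n_layers: int
    deltas: list[float] = field(default_factory=list)
    converged: bool = True


def aggregate_neighbors(graph: FeatureGraph, node: int) -> np.ndarray:
    """Edge-weighted mean of a node's neighbor embeddings.

    Returns sum_j h_j * w_ij / |N(i)|; the zero vector for an isolated
    node.
    """
    acc = np.zeros(graph.embeddings.shape[1])
    count = 0
    for (i, j), w in graph.edges.items():
        if i == node:
            acc += graph.embeddings[j] * w
            count += 1
        elif j == node:
            acc += graph.embeddings[i] * w
            count += 1
    return acc / count if count else acc


def _aggregate_all(graph: FeatureGraph) -> np.ndarray:
    """Vectorized neighborhood aggregate for every node at once."""
    h = graph.embeddings
    agg = np.zeros_like(h)
    deg = np.zeros(graph.n_nodes)
    for (i, j), w in graph.edges.items():
        agg[i] += h[j] * w
        agg[j] += h[i] * w
        deg[i] += 1
        deg[j] += 1
    nz = deg > 0
    agg[nz] /= deg[nz, None]
    return agg


def propagate_step(graph: FeatureGraph, config: PropagationConfig) -> FeatureGraph:
    """One synchronous propagation layer; returns a new graph.

    For each node: ``c = sigma(concat(h, aggregate))``; the new embedding
    is the elementwise mean of the two halves of ``c``, renormalized to
    unit L2 norm.  A node whose update collapses to the zero vector keeps
    its previous embedding.
    """
    sigma = config.sigma()
    h = graph.embeddings
    agg = _aggregate_all(graph)
    c = sigma(np.concatenate([h, agg], axis=1))
    d = h.shape[1]
    new = (c[:, :d] + c[:, d:]) / 2.0
    norms = np.linalg.norm(new, axis=1)
    zero = norms == 0
    if zero.any():
        logger.info("%d nodes had zero-norm updates; keeping previous embeddings", zero.sum())
        new[zero] = h[zero]
        norms[zero] = np.linalg.norm(h[zero], axis=1)
        norms[norms == 0] = 1.0
    new /= norms[:, None]
    return FeatureGraph(
        node_ids=list(graph.node_ids),
        edges=dict(graph.edges),
        embeddings=new,
        layer=graph.layer + 1,
    )


def propagate_to_convergence(
    graph: FeatureGraph, config: PropagationConfig | None = None
) -> PropagationResult:
    """Repeat propagation steps until embeddings stabilize.

    Stops when ``max_i ||h^K_i - h^{K-1}_i||_2 < epsilon`` or
    ``max_layers`` is reached (result flagged, no exception).  Returns
    the final graph and the number of layers L.
    """
    config = config or PropagationConfig()
    deltas: list[float] = []
    current = graph
    for _ in range(config.max_layers):
        nxt = propagate_step(current, config)
        delta = float(np.linalg.norm(nxt.embeddings - current.embeddings, axis=1).max())
        deltas.append(delta)
        current = nxt
        if delta < config.epsilon:
            return PropagationResult(graph=current, n_layers=current.layer, deltas=deltas)
    logger.warning("propagation hit max_layers=%d without converging", config.max_layers)
    return PropagationResult(
        graph=current, n_layers=current.layer, deltas=deltas, converged=False
    )
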