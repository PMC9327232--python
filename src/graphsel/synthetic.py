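"""Synthetic microarray-style data with planted redundancy blocks.

The generator emulates the regimes of two-class microarray cohorts:
many more features than samples, configurable class imbalance,
correlated feature blocks driven by shared latent factors, and a
partially observed prior network consistent with the blocks.

Model
-----
Each block b has a per-sample latent factor g_b ~ N(0, 1).  A block
feature is ``x = lambda * g_b + sqrt(1 - lambda^2) * N(0, 1)``, so the
expected within-block correlation is lambda^2.  Informative blocks have
their latent factor shifted by the effect size delta (in within-class
sd units) for class-1 samples.  Background features are pure N(0, 1)
noise.  Prior edges appear within blocks with probability ``p_in``
(weight U(0.5, 1)) and between any other pair with probability
``p_out``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from graphsel.dataio import ExpressionDataset, PriorNetwork
from graphsel.errors import ValidationError


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block generator.

    ``planted_feature_per_block`` additionally shifts one designated
    feature per informative block by ``effect_size`` directly, making it
    the uniquely strongest marker of its block (used to test exact
    recovery of a known best feature).
    """

    n_samples: int = 60
    n_features: int = 500
    n_blocks: int = 4
    block_size: int = 10
    loading: float = 0.8  # within-block factor loading lambda
    effect_size: float = 1.5  # class shift delta, within-class sd units
    class_balance: float = 0.5
    p_in: float = 0.8
    p_out: float = 0.02
    planted_feature_per_block: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks * self.block_size > self.n_features:
            raise ValidationError("blocks do not fit into n_features")
        if not 0 < self.loading < 1:
            raise ValidationError("loading must be in (0, 1)")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValidationError("need 0 <= p_out <= p_in <= 1")
        if not 0 < self.class_balance < 1:
            raise ValidationError("class_balance must be in (0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for test oracles."""

    block_of_feature: np.ndarray  # 0 = background, 1..n_blocks
    informative_blocks: list[bool]
    prior_edges: list[tuple[str, str]]
    planted_features: list[str] = field(default_factory=list)
    heldout_edges: list[tuple[str, str]] = field(default_factory=list)


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, PriorNetwork, GroundTruth]:
    """Generate (dataset, prior network, ground truth), seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_samples, spec.n_features
    n_pos = min(m - 1, max(1, int(round(spec.class_balance * m))))
    labels = np.zeros(m, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    feature_ids = [f"F{i:04d}" for i in range(n)]
    sample_ids = [f"s{i:03d}" for i in range(m)]
    block_of = np.zeros(n, dtype=int)
    values = rng.standard_normal((m, n))
    lam = spec.loading
    noise_scale = np.sqrt(1.0 - lam**2)
    informative = [True] * spec.n_blocks
    planted: list[str] = []
    for b in range(spec.n_blocks):
        cols = range(b * spec.block_size, (b + 1) * spec.block_size)
        g = rng.standard_normal(m)
        if informative[b]:
            g = g + spec.effect_size * labels
        for c in cols:
            block_of[c] = b + 1
            values[:, c] = lam * g + noise_scale * rng.standard_normal(m)
        if spec.planted_feature_per_block and informative[b]:
            c0 = b * spec.block_size
            values[:, c0] += spec.effect_size * labels
            planted.append(feature_ids[c0])

    weights: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            same_block = block_of[i] != 0 and block_of[i] == block_of[j]
            p = spec.p_in if same_block else spec.p_out
            if p > 0 and rng.random() < p:
                weights[(feature_ids[i], feature_ids[j])] = float(rng.uniform(0.5, 1.0))
    ds = ExpressionDataset(
        values=values, labels=labels, feature_ids=feature_ids, sample_ids=sample_ids
    )
    net = PriorNetwork(weights=weights)
    truth = GroundTruth(
        block_of_feature=block_of,
        informative_blocks=informative,
        prior_edges=sorted(weights),
        planted_features=planted,
    )
    return ds, net, truth


def split_heldout_edges(
    net: PriorNetwork, frac: float, seed: int = 0
) -> tuple[PriorNetwork, list[tuple[str, str]]]:
    """Uniformly split a prior network into train edges and held-out edges.

    At least one edge is always held out; the train set may not end up
    empty.
    """
    if not 0 < frac < 1:
        raise ValidationError("frac must be in (0, 1)")
    edges = sorted(net.weights)
    m = len(edges)
    if m < 2:
        raise ValidationError("network needs at least 2 edges to split")
    n_test = max(1, int(round(frac * m)))
    if n_test >= m:
        raise ValidationError("split would empty the train set")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(m, size=n_test, replace=False).tolist())
    test = [edges[i] for i in sorted(test_idx)]
    train = {e: net.weights[e] for k, e in enumerate(edges) if k not in test_idx}
    return PriorNetwork(weights=train), test
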