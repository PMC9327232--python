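import numpy as np
import pytest

from graphsel.dataio import ExpressionDataset, PriorNetwork
from graphsel.graphbuild import FeatureGraph
from graphsel.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_synthetic():
    """Default-condition synthetic cohort (60 samples x 500 features)."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_synthetic():
    """Small planted-block cohort for fast end-to-end checks."""
    spec = SyntheticSpec(
        n_samples=60,
        n_features=60,
        n_blocks=4,
        block_size=10,
        planted_feature_per_block=True,
        seed=3,
    )
    return generate_dataset(spec)


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(0)
    values = rng.standard_normal((12, 5))
    labels = np.array([0, 1] * 6)
    return ExpressionDataset(
        values=values,
        labels=labels,
        feature_ids=[f"g{i}" for i in range(5)],
        sample_ids=[f"s{i}" for i in range(12)],
    )


def make_graph(n_nodes, edges, embeddings=None, d=2):
    """Helper to build a FeatureGraph from an index-keyed edge dict."""
    if embeddings is None:
        rng = np.random.default_rng(0)
        embeddings = rng.standard_normal((n_nodes, d))
        embeddings /= np.linalg.norm(embeddings, axis=1, keepdims=True)
    return FeatureGraph(
        node_ids=[f"n{i}" for i in range(n_nodes)],
        edges={tuple(sorted(e)): w for e, w in edges.items()},
        embeddings=np.asarray(embeddings, dtype=float),
    )
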