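"""Link prediction: sampling, loss, gradient, MRR, augmentation."""

import math

import numpy as np
import pytest

from graphsel.errors import NegativeSamplingError, ValidationError
from graphsel.linkpred import (
    EdgeSampleSet,
    TrainConfig,
    augment_graph,
    cosine_similarity,
    lp_loss,
    lp_loss_grad,
    mrr,
    positive_ranks,
    sample_pos_neg,
    train_link_predictor,
)
from graphsel.propagate import PropagationConfig, propagate_to_convergence
from conftest import make_graph


def _random_graph(n=10, p=0.45, seed=0, d=6):
    rng = np.random.default_rng(seed)
    edges = {
        (i, j): float(rng.uniform(0.1, 1.0))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    emb = rng.standard_normal((n, d))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    return make_graph(n, edges, embeddings=emb)


def _block_graph(n_blocks=3, size=6, seed=0, d=8):
    """Planted-block graph: dense within blocks, block-specific embeddings."""
    rng = np.random.default_rng(seed)
    n = n_blocks * size
    edges = {}
    centers = rng.standard_normal((n_blocks, d)) * 3
    emb = np.zeros((n, d))
    for b in range(n_blocks):
        nodes = range(b * size, (b + 1) * size)
        for i in nodes:
            emb[i] = centers[b] + 0.2 * rng.standard_normal(d)
            for j in nodes:
                if i < j and rng.random() < 0.8:
                    edges[(i, j)] = float(rng.uniform(0.5, 1.0))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    return make_graph(n, edges, embeddings=emb), size


class TestSampling:
    def test_complete_graph_has_no_negatives(self):
        n = 5
        g = make_graph(n, {(i, j): 0.5 for i in range(n) for j in range(i + 1, n)})
        with pytest.raises(NegativeSamplingError):
            sample_pos_neg(g, holdout_frac=0.2, neg_per_pos=5, seed=0)

    def test_counting_contract(self):
        g = _random_graph(n=10, p=0.45, seed=3)
        m = g.n_edges()
        reduced, sample = sample_pos_neg(g, holdout_frac=0.1, neg_per_pos=5, seed=1)
        n_pos = math.ceil(0.1 * m)
        assert len(sample.pos) == n_pos
        assert len(sample.all_neg()) == 5 * n_pos
        assert reduced.n_edges() == m - n_pos
        # held-out edges are gone; negatives never touch true edges
        assert all(e not in reduced.edges for e in sample.pos)
        assert all(e not in g.edges for e in sample.all_neg())

    def test_seed_determinism(self):
        g = _random_graph(seed=2)
        _, s1 = sample_pos_neg(g, seed=42)
        _, s2 = sample_pos_neg(g, seed=42)
        assert s1.pos == s2.pos and s1.neg == s2.neg


class TestCosine:
    def test_identical(self):
        v = np.array([1.0, 2.0, -1.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_value(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])
        assert cosine_similarity(a, b) == pytest.approx(10 / 14)

    def test_zero_vector_raises(self):
        with pytest.raises(ValidationError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestLoss:
    def test_orthogonal_pair_hand_value(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        sample = EdgeSampleSet(pos=[(0, 1)], neg=[[(2, 3)]], neg_per_pos=1, seed=0)
        assert lp_loss(z, sample) == pytest.approx(2 * math.log(2))

    def test_saturated_limit_goes_to_zero(self):
        # positive pair aligned, negative pair anti-aligned, scaled scores
        z = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        sample = EdgeSampleSet(pos=[(0, 1)], neg=[[(2, 3)]], neg_per_pos=1, seed=0)
        # cosine is bounded; loss floor is 2*(-log sigmoid(1)) > 0 but small
        assert lp_loss(z, sample) < 2 * math.log(2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((8, 4))
        pos = [(0, 1), (2, 3), (4, 5)]
        neg = [[(1, 2), (3, 4)], [(5, 6), (6, 7)], [(0, 7), (2, 6)]]
        s1 = EdgeSampleSet(pos=pos, neg=neg, neg_per_pos=2, seed=0)
        s2 = EdgeSampleSet(pos=pos[::-1], neg=neg[::-1], neg_per_pos=2, seed=0)
        assert lp_loss(z, s1) == pytest.approx(lp_loss(z, s2))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((6, 4))
        sample = EdgeSampleSet(
            pos=[(0, 1), (2, 3)],
            neg=[[(1, 4), (4, 5)], [(0, 5), (3, 5)]],
            neg_per_pos=2,
            seed=0,
        )
        grad = lp_loss_grad(z, sample)
        eps = 1e-6
        num = np.zeros_like(z)
        for i in range(z.shape[0]):
            for k in range(z.shape[1]):
                zp, zm = z.copy(), z.copy()
                zp[i, k] += eps
                zm[i, k] -= eps
                num[i, k] = (lp_loss(zp, sample) - lp_loss(zm, sample)) / (2 * eps)
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-8)


class TestMRR:
    def test_perfect_scorer(self):
        assert mrr([1, 1, 1]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert mrr([1, 2, 4]) == pytest.approx((1 + 0.5 + 0.25) / 3)

    def test_worst_case_closed_form(self):
        k = 5
        assert mrr([k + 1] * 4) == pytest.approx(1 / (k + 1))

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            mrr([])

    def test_matches_brute_force_rank_count(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_pos, k = rng.integers(2, 6), rng.integers(2, 7)
            pos_scores = rng.standard_normal(n_pos)
            neg_scores = rng.standard_normal((n_pos, k))
            ranks = [1 + int((neg_scores[t] > pos_scores[t]).sum()) for t in range(n_pos)]
            expected = float(np.mean([1 / r for r in ranks]))
            assert mrr(ranks) == pytest.approx(expected)
            assert 1 / (k + 1) <= mrr(ranks) <= 1.0


class TestTraining:
    def test_fixed_seed_identical_traces(self):
        g, _ = _block_graph(seed=5)
        reduced, sample = sample_pos_neg(g, seed=5)
        m1 = train_link_predictor(reduced, sample, TrainConfig(max_epochs=20))
        m2 = train_link_predictor(reduced, sample, TrainConfig(max_epochs=20))
        assert m1.loss_trace == m2.loss_trace
        np.testing.assert_array_equal(m1.best_z, m2.best_z)

    def test_loss_decreases_early(self):
        g, _ = _block_graph(seed=1)
        reduced, sample = sample_pos_neg(g, seed=1)
        model = train_link_predictor(reduced, sample, TrainConfig(max_epochs=30))
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_mrr_improves_over_initialization(self):
        wins = 0
        for seed in range(10):
            g, _ = _block_graph(seed=seed)
            reduced, sample = sample_pos_neg(g, seed=seed)
            init_mrr = mrr(positive_ranks(reduced.embeddings, sample))
            model = train_link_predictor(reduced, sample, TrainConfig(max_epochs=50))
            wins += max(model.mrr_trace) >= init_mrr
        assert wins >= 8  # improvement in the clear majority of replicates

    def test_huge_stop_threshold_stops_after_two_epochs(self):
        g, _ = _block_graph(seed=2)
        reduced, sample = sample_pos_neg(g, seed=2)
        model = train_link_predictor(reduced, sample, TrainConfig(stop_epsilon=1e6))
        assert len(model.loss_trace) == 2

    def test_mrr_trace_in_unit_interval(self):
        g, _ = _block_graph(seed=3)
        reduced, sample = sample_pos_neg(g, seed=3)
        model = train_link_predictor(reduced, sample, TrainConfig(max_epochs=15))
        assert all(0 < v <= 1 for v in model.mrr_trace)


class TestAugmentation:
    def test_add_frac_zero_restores_heldout_only(self):
        g, _ = _block_graph(seed=4)
        reduced, sample = sample_pos_neg(g, seed=4)
        model = train_link_predictor(reduced, sample, TrainConfig(max_epochs=10))
        star = augment_graph(reduced, model, sample=sample, add_frac=0.0)
        assert set(star.edges) == set(g.edges)
        for e in sample.pos:
            assert star.edges[e] == g.edges[e]

    def test_edge_counting_contract(self):
        g, _ = _block_graph(seed=6)
        reduced, sample = sample_pos_neg(g, seed=6)
        model = train_link_predictor(reduced, sample, TrainConfig(max_epochs=10))
        star = augment_graph(reduced, model, sample=sample, add_frac=0.1)
        k = math.ceil(0.1 * reduced.n_edges())
        assert len(star.added_edges) == k
        assert star.n_edges() == reduced.n_edges() + k + len(sample.pos)
        assert all(0 < w <= 1 for w in star.edges.values())

    def test_added_edges_mostly_within_planted_blocks(self):
        g, size = _block_graph(n_blocks=3, size=6, seed=8)
        reduced, sample = sample_pos_neg(g, holdout_frac=0.1, seed=8)
        model = train_link_predictor(reduced, sample, TrainConfig(max_epochs=50))
        star = augment_graph(reduced, model, sample=sample, add_frac=0.1)
        within = sum(1 for i, j, _ in star.added_edges if i // size == j // size)
        assert within / len(star.added_edges) >= 0.7
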