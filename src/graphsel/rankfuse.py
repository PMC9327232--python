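"""Per-cluster feature ranking by eight evaluators plus RRA fusion.

Each redundancy sub-cluster is ranked by eight evaluators — L1- and
L2-regularized logistic models, ordinary least squares, Welch t-test,
feature-label Pearson correlation, decision tree, random forest, and
stability selection — and the eight rank lists are fused with Robust
Rank Aggregation (RRA): a feature's score is the minimum over k of the
Beta(k, n-k+1) CDF at its k-th smallest normalized rank, small scores
marking consistently top-ranked features.  The best-scoring feature of
each sub-cluster is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from graphsel.dataio import ExpressionDataset
from graphsel.errors import ValidationError
from graphsel.speclust import ClusterPartition

logger = logging.getLogger(__name__)

EVALUATORS = (
    "l1",
    "l2",
    "ttest",
    "correlation",
    "decision_tree",
    "random_forest",
    "stability_selection",
    "linear_regression",
)

N_STABILITY_SUBSAMPLES = 100
STABILITY_SAMPLE_FRAC = 0.75
STABILITY_SCALE_RANGE = (0.5, 1.0)


@dataclass
class RankList:
    """One evaluator's ordered feature ids (rank 1 = most important)."""

    evaluator_name: str
    feature_ids: list[str]
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class AggregatedRanking:
    """RRA scores and the fused order (ascending rho)."""

    feature_ids: list[str]  # final order
    rho: dict[str, float]
    corrected: dict[str, float]


@dataclass
class SelectionResult:
    """One selected feature per non-empty sub-cluster, with provenance."""

    selected: list[str]
    cluster_rankings: list[AggregatedRanking]
    cluster_features: list[list[str]]
    provenance: dict = field(default_factory=dict)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _importances(x: np.ndarray, y: np.ndarray, method: str, seed: int) -> np.ndarray:
    """Per-feature importance scores (larger = more important)."""
    xs = _standardize(x)
    if method == "l1":
        model = LogisticRegression(C=1.0, l1_ratio=1.0, solver="liblinear", random_state=seed)
        model.fit(xs, y)
        return np.abs(model.coef_[0])
    if method == "l2":
        model = LogisticRegression(C=1.0, l1_ratio=0.0, solver="liblinear", random_state=seed)
        model.fit(xs, y)
        return np.abs(model.coef_[0])
    if method == "linear_regression":
        model = LinearRegression()
        model.fit(xs, y)
        return np.abs(model.coef_)
    if method == "ttest":
        pos, neg = x[y == 1], x[y == 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
        return np.nan_to_num(np.abs(t), nan=0.0)
    if method == "correlation":
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc.T @ yc) / denom
        return np.nan_to_num(np.abs(r), nan=0.0)
    if method == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed)
        model.fit(xs, y)
        return model.feature_importances_
    if method == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
        model.fit(xs, y)
        return model.feature_importances_
    if method == "stability_selection":
        return _stability_selection(xs, y, seed)
    raise ValidationError(f"unknown evaluator {method!r}")


def _stability_selection(xs: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Selection frequency of a nonzero L1 coefficient over subsamples.

    Randomized-lasso style: each subsample of 75% of the rows rescales
    every feature column by a factor drawn uniformly from [0.5, 1]
    (equivalent to a per-feature penalty scaling) before the L1 fit.
    """
    rng = np.random.default_rng(seed)
    m, n = xs.shape
    n_sub = max(2, int(round(STABILITY_SAMPLE_FRAC * m)))
    freq = np.zeros(n)
    n_done = 0
    for _ in range(N_STABILITY_SUBSAMPLES):
        rows = rng.choice(m, size=n_sub, replace=False)
        if len(np.unique(y[rows])) < 2:
            continue
        scale = rng.uniform(*STABILITY_SCALE_RANGE, size=n)
        model = LogisticRegression(C=1.0, l1_ratio=1.0, solver="liblinear", random_state=0)
        model.fit(xs[rows] * scale, y[rows])
        freq += model.coef_[0] != 0
        n_done += 1
    return freq / max(n_done, 1)


def rank_features(
    ds: ExpressionDataset, method: str, seed: int = 0
) -> RankList:
    """Rank a (sub-cluster) dataset's features with one evaluator.

    Order is descending importance with lexicographic feature-id
    tie-break; a single-feature input needs no model fit.
    """
    if method not in EVALUATORS:
        raise ValidationError(f"unknown evaluator {method!r}")
    if ds.n_features == 1:
        return RankList(evaluator_name=method, feature_ids=list(ds.feature_ids),
                        scores={ds.feature_ids[0]: 1.0})
    imp = _importances(ds.values, ds.labels, method, seed)
    order = sorted(range(ds.n_features), key=lambda i: (-imp[i], ds.feature_ids[i]))
    ids = [ds.feature_ids[i] for i in order]
    return RankList(
        evaluator_name=method,
        feature_ids=ids,
        scores={ds.feature_ids[i]: float(imp[i]) for i in range(ds.n_features)},
    )


def rra_aggregate(rank_lists: list[RankList]) -> AggregatedRanking:
    """Fuse rank lists with the Beta order-statistic RRA score.

    For each feature the normalized ranks r = rank/m across the n lists
    are sorted ascending; rho = min_k BetaCDF(r_(k); k, n-k+1).  The
    fused order is ascending rho, ties broken by feature id; the
    corrected score is min(1, rho * m).
    """
    if not rank_lists:
        raise ValidationError("need at least one rank list")
    universe = sorted(rank_lists[0].feature_ids)
    for rl in rank_lists[1:]:
        if sorted(rl.feature_ids) != universe:
            raise ValidationError("rank lists cover different feature sets")
    m = len(universe)
    n = len(rank_lists)
    rho: dict[str, float] = {}
    for fid in universe:
        r = np.sort([(rl.feature_ids.index(fid) + 1) / m for rl in rank_lists])
        k = np.arange(1, n + 1)
        rho[fid] = float(np.min(stats.beta.cdf(r, k, n - k + 1)))
    order = sorted(universe, key=lambda f: (rho[f], f))
    corrected = {f: min(1.0, rho[f] * m) for f in universe}
    return AggregatedRanking(feature_ids=order, rho=rho, corrected=corrected)


def select_per_cluster(
    partition: ClusterPartition, ds: ExpressionDataset, seed: int = 0
) -> SelectionResult:
    """Run all eight evaluators per sub-cluster and pick the RRA winner.

    Empty clusters are skipped with a warning, so the selected subset
    size equals the number of non-empty clusters.
    """
    clusters = partition.clusters()
    selected: list[str] = []
    rankings: list[AggregatedRanking] = []
    kept_features: list[list[str]] = []
    for c, feats in enumerate(clusters):
        if not feats:
            logger.warning("cluster %d is empty; skipped", c)
            continue
        sub = ds.subset_features(feats)
        lists = [rank_features(sub, method, seed=seed) for method in EVALUATORS]
        agg = rra_aggregate(lists)
        selected.append(agg.feature_ids[0])
        rankings.append(agg)
        kept_features.append(feats)
    return SelectionResult(
        selected=selected,
        cluster_rankings=rankings,
        cluster_features=kept_features,
        provenance={"seed": seed, "evaluators": list(EVALUATORS)},
    )
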