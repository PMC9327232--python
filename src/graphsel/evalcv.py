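"""Cross-validated evaluation of selected feature subsets.

A feature subset is scored by stratified k-fold cross-validation (10
folds by default) with an RBF support-vector classifier (C = 1.0,
kernel width scaled by feature count and variance).  Features are
standardized inside each fold using training-fold statistics only; AUC
comes from decision-function scores.  ``cluster_sweep`` reruns the
clustering/selection/CV tail of the pipeline for a range of cluster
counts while sharing the expensive upstream stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from graphsel.dataio import ExpressionDataset
from graphsel.errors import ValidationError
from graphsel.rankfuse import select_per_cluster
from graphsel.speclust import SpectralConfig, spectral_partition

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Mean and per-fold accuracy/AUC of a stratified k-fold run."""

    acc: float
    auc: float
    fold_acc: list[float]
    fold_auc: list[float]
    k: int
    seed: int


def cross_validate(
    ds: ExpressionDataset, feature_subset: list[str], k: int = 10, seed: int = 0
) -> CVResult:
    """Stratified k-fold SVM evaluation of a feature subset.

    ``k`` is reduced (with a warning) if the smaller class has fewer
    than ``k`` samples.
    """
    if not feature_subset:
        raise ValidationError("feature subset is empty")
    sub = ds.subset_features(list(feature_subset))
    y = sub.labels
    min_class = int(min((y == 1).sum(), (y == 0).sum()))
    if min_class < 2:
        raise ValidationError("each class needs at least 2 samples for stratified CV")
    if min_class < k:
        warnings.warn(f"reducing folds from {k} to {min_class} (smallest class size)")
        k = min_class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc, fold_auc = [], []
    for train, test in skf.split(sub.values, y):
        clf = make_pipeline(StandardScaler(), SVC(C=1.0, kernel="rbf", gamma="scale"))
        clf.fit(sub.values[train], y[train])
        pred = clf.predict(sub.values[test])
        scores = clf.decision_function(sub.values[test])
        fold_acc.append(float(accuracy_score(y[test], pred)))
        if len(np.unique(y[test])) == 2:
            fold_auc.append(float(roc_auc_score(y[test], scores)))
    auc = float(np.mean(fold_auc)) if fold_auc else float("nan")
    return CVResult(
        acc=float(np.mean(fold_acc)),
        auc=auc,
        fold_acc=fold_acc,
        fold_auc=fold_auc,
        k=k,
        seed=seed,
    )


def cluster_sweep(ds, prior, mu_values, config=None) -> list[dict]:
    """Accuracy/AUC as a function of the cluster count.

    Runs the shared pipeline stages (prefilter, graph construction,
    propagation, link prediction) once, then clusters, selects and
    cross-validates per cluster count.  Returns one row dict per value
    of ``mu``.
    """
    from graphsel.pipeline import PipelineConfig, prepare_augmented_graph

    config = config or PipelineConfig()
    filtered, graph_star, _report = prepare_augmented_graph(ds, prior, config)
    rows = []
    for mu in mu_values:
        if mu > graph_star.n_nodes:
            raise ValidationError(f"mu={mu} exceeds node count {graph_star.n_nodes}")
        part = spectral_partition(
            graph_star,
            SpectralConfig(mu=mu, kmeans_restarts=config.kmeans_restarts, seed=config.seed),
        )
        sel = select_per_cluster(part, filtered, seed=config.seed)
        cv = cross_validate(ds, sel.selected, k=config.cv_folds, seed=config.seed)
        rows.append(
            {"mu": mu, "n_selected": len(sel.selected), "acc": cv.acc, "auc": cv.auc}
        )
        logger.info("sweep mu=%d: %d features, acc=%.3f auc=%.3f", mu, len(sel.selected), cv.acc, cv.auc)
    return rows
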