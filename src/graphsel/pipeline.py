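"""End-to-end orchestration of the selection pipeline.

Stage order: Welch t-test prefilter -> feature-graph construction ->
message propagation to convergence -> link-prediction training and
graph augmentation -> spectral clustering -> per-cluster eight-evaluator
ranking with RRA fusion.  All stage defaults follow the experimental
setup: 100 features retained by the prefilter, convergence threshold
0.01, 4 clusters.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass
from pathlib import Path

from graphsel.dataio import (
    ExpressionDataset,
    PriorNetwork,
    read_expression,
    read_prior_network,
    ttest_prefilter,
)
from graphsel.errors import GraphselError
from graphsel.evalcv import cross_validate
from graphsel.graphbuild import FeatureGraph, build_graph
from graphsel.linkpred import (
    TrainConfig,
    augment_graph,
    sample_pos_neg,
    train_link_predictor,
)
from graphsel.propagate import PropagationConfig, propagate_to_convergence
from graphsel.rankfuse import SelectionResult, select_per_cluster
from graphsel.speclust import SpectralConfig, spectral_partition

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of one selection run."""

    keep: int = 100          # features retained by the t-test prefilter
    epsilon: float = 0.01    # propagation convergence threshold
    mu: int = 4              # number of spectral clusters
    r_min: float = 0.7       # |Pearson r| threshold for candidate edges
    activation: str = "tanh"
    max_layers: int = 50
    holdout_frac: float = 0.1
    neg_per_pos: int = 5
    add_frac: float = 0.1
    learning_rate: float = 0.01
    train_epsilon: float = 1e-4
    max_epochs: int = 200
    kmeans_restarts: int = 10
    cv_folds: int = 10
    seed: int = 0


def prepare_augmented_graph(
    ds: ExpressionDataset, prior: PriorNetwork, config: PipelineConfig
):
    """Run the shared upstream stages.

    Returns (filtered dataset, augmented graph G*, stage report dict).

    Also usable standalone so that cluster-count sweeps can reuse the
    expensive graph/propagation/link-prediction work.
    """
    filtered = ttest_prefilter(ds, keep=config.keep)
    graph = build_graph(filtered, prior.restrict(set(filtered.feature_ids)), r_min=config.r_min)
    prop = propagate_to_convergence(
        graph,
        PropagationConfig(
            epsilon=config.epsilon, activation=config.activation, max_layers=config.max_layers
        ),
    )
    reduced, sample = sample_pos_neg(
        prop.graph,
        holdout_frac=config.holdout_frac,
        neg_per_pos=config.neg_per_pos,
        seed=config.seed,
    )
    model = train_link_predictor(
        prop,
        sample,
        TrainConfig(
            learning_rate=config.learning_rate,
            stop_epsilon=config.train_epsilon,
            max_epochs=config.max_epochs,
        ),
    )
    # the trained model scores non-edges of the reduced graph
    star = augment_graph(reduced, model, sample=sample, add_frac=config.add_frac)
    report = {
        "n_layers": prop.n_layers,
        "propagation_deltas": prop.deltas,
        "converged": prop.converged,
        "loss_trace": model.loss_trace,
        "mrr_trace": model.mrr_trace,
        "n_edges_initial": graph.n_edges(),
        "n_edges_augmented": star.n_edges(),
    }
    return filtered, star, report


def run_selection(
    config: PipelineConfig,
    ds: ExpressionDataset | None = None,
    prior: PriorNetwork | None = None,
    expr_path=None,
    labels_path=None,
    prior_path=None,
    out_dir=None,
) -> SelectionResult:
    """Execute the full selection pipeline and optionally write outputs.

    Outputs (when ``out_dir`` is given): ``selected_features.tsv``
    (cluster_id, probe_id, rra_score), ``rankings.tsv`` (full per-cluster
    aggregated rankings), ``edges_initial.tsv``/``edges_augmented.tsv``,
    and ``report.json`` with convergence and training traces.  A stage
    failure removes partial outputs.
    """
    if ds is None:
        ds = read_expression(expr_path, labels_path)
    if prior is None:
        prior = read_prior_network(prior_path, feature_universe=ds.feature_ids)
    out = Path(out_dir) if out_dir is not None else None
    try:
        t0 = time.time()
        filtered, star, report = prepare_augmented_graph(ds, prior, config)
        part = spectral_partition(
            star,
            SpectralConfig(mu=config.mu, kmeans_restarts=config.kmeans_restarts, seed=config.seed),
        )
        result = select_per_cluster(part, filtered, seed=config.seed)
        result.provenance.update({"config": asdict(config)})
        report.update(
            {
                "eigenvalues": [float(v) for v in part.eigenvalues],
                "selected": result.selected,
                "seed": config.seed,
                "config": asdict(config),
            }
        )
        logger.info("selection finished in %.1fs: %s", time.time() - t0, result.selected)
        if out is not None:
            _write_outputs(out, result, star, part, report)
        return result
    except GraphselError:
        if out is not None and out.exists():
            shutil.rmtree(out, ignore_errors=True)
        raise


def _write_outputs(out: Path, result: SelectionResult, star, part, report: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "selected_features.tsv", "w") as fh:
        fh.write("cluster_id\tprobe_id\trra_score\n")
        for c, (fid, agg) in enumerate(zip(result.selected, result.cluster_rankings)):
            fh.write(f"{c}\t{fid}\t{agg.rho[fid]:.10g}\n")
    with open(out / "rankings.tsv", "w") as fh:
        fh.write("cluster_id\trank\tprobe_id\trra_score\tcorrected\n")
        for c, agg in enumerate(result.cluster_rankings):
            for rank, fid in enumerate(agg.feature_ids, start=1):
                fh.write(
                    f"{c}\t{rank}\t{fid}\t{agg.rho[fid]:.10g}\t{agg.corrected[fid]:.10g}\n"
                )
    added = {(i, j) for i, j, _ in getattr(star, "added_edges", [])}
    with open(out / "edges_augmented.tsv", "w") as fh:
        fh.write("feature_a\tfeature_b\tweight\tpredicted\n")
        for (i, j), w in sorted(star.edges.items()):
            flag = 1 if (i, j) in added else 0
            fh.write(f"{star.node_ids[i]}\t{star.node_ids[j]}\t{w:.10g}\t{flag}\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
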