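"""End-to-end orchestration: preprocess -> stats -> graph -> walk -> activity
-> rank -> evaluate, with artifacts and a provenance record on disk."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__
from .activity import PathwayActivityMatrix, build_activity_matrix
from .autoencoder import rank_by_da, save_model, train
from .diffstats import nb_wald_test, welch_t_test, write_stats
from .evaluate import (baseline_drw_concat, baseline_mean_median, cross_validate,
                       rank_by_ttest)
from .graph import build_integrated_graph, build_layer_graph, row_normalize
from .io import (EXPRESSION, METHYLATION, derive_groups, filter_low_expression, impute_median,
                 read_edge_list, read_gmt, read_matrix, write_labels, zscore)
from .walk import initial_weights, random_walk, write_node_weights

log = logging.getLogger(__name__)

MODES = ("idrw", "idrw_anti", "drw_concat", "mean", "median", "gene_profile")
RANKERS = ("ttest", "da")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run (defaults = reference values)."""

    expr_path: str
    meth_path: str
    clinical_path: str
    graph_path: str
    gmt_path: str
    out_dir: str = "idrw_out"
    mode: str = "idrw"
    ranker: str = "ttest"
    restart_prob: float = 0.7
    walk_tol: float = 1e-10
    alpha: float = 0.05
    threshold_days: int = 1095
    hidden: int = 200
    corruption: float = 0.1
    lr: float = 0.01
    epochs: int = 500
    batch_size: int = 32
    folds: int = 5
    repeats: int = 10
    max_n: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.ranker not in RANKERS:
            raise ValueError(f"ranker must be one of {RANKERS}")
        if not 0 < self.restart_prob <= 1:
            raise ValueError("restart_prob must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("folds", "repeats", "hidden", "epochs", "batch_size", "max_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preprocess(config: RunConfig):
    """Load inputs and apply the cohort filters; returns aligned matrices."""
    expr = read_matrix(config.expr_path, EXPRESSION, "raw_counts")
    meth = read_matrix(config.meth_path, METHYLATION, "continuous")
    labels = derive_groups(config.clinical_path, config.threshold_days)
    shared = [s for s in labels.sample_ids
              if s in set(expr.sample_ids) and s in set(meth.sample_ids)]
    if not shared:
        raise ValueError("no labelled sample is present in both omics layers")
    labels = labels.subset(shared)
    expr = filter_low_expression(expr.subset_samples(shared))
    meth = impute_median(meth.subset_samples(shared))
    return expr, meth, labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline and write all artifacts under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"mode": config.mode, "ranker": config.ranker}

    def stage(name):
        log.info("[%s] %.1fs elapsed", name, time.time() - t0)

    expr, meth, labels = preprocess(config)
    write_labels(labels, out / "labels.tsv")
    stage("preprocess")

    expr_stats = nb_wald_test(expr, labels)
    meth_stats = welch_t_test(meth, labels)
    write_stats(expr_stats, out / "stats_expression.tsv")
    write_stats(meth_stats, out / "stats_methylation.tsv")
    stats = expr_stats + meth_stats
    stage("diffstats")

    base = read_edge_list(config.graph_path)
    pathdb = read_gmt(config.gmt_path)
    zmats = {EXPRESSION: zscore(expr), METHYLATION: zscore(meth)}

    if config.mode in ("idrw", "idrw_anti"):
        graph = build_integrated_graph(
            base, expr, meth, mode="anti" if config.mode == "idrw_anti" else "all",
            alpha=config.alpha)
        graph.write_edges(out / "graph.tsv")
        winf = random_walk(row_normalize(graph), initial_weights(stats, graph),
                           r=config.restart_prob, tol=config.walk_tol)
        write_node_weights(winf, out / "winf.tsv")
        stage("walk")
        act = build_activity_matrix(pathdb, stats, winf, zmats, config.alpha)
    elif config.mode == "drw_concat":
        per_layer = []
        for matrix, layer_stats in ((expr, expr_stats), (meth, meth_stats)):
            g = build_layer_graph(base, matrix)
            winf = random_walk(row_normalize(g), initial_weights(layer_stats, g),
                               r=config.restart_prob, tol=config.walk_tol)
            per_layer.append(build_activity_matrix(
                pathdb, layer_stats, winf, {matrix.layer: zmats[matrix.layer]},
                config.alpha))
        act = baseline_drw_concat(*per_layer)
        stage("walk")
    elif config.mode in ("mean", "median"):
        act = baseline_mean_median(zmats, pathdb, stats, stat=config.mode,
                                   alpha=config.alpha)
    else:  # gene_profile: concatenated z-scored gene features, no pathway step
        frames = [zmats[EXPRESSION].values.rename(index=lambda g: f"{g}@{EXPRESSION}"),
                  zmats[METHYLATION].values.rename(index=lambda g: f"{g}@{METHYLATION}")]
        act = PathwayActivityMatrix(pd.concat(frames))
    act.write(out / "activity.tsv", out / "activity_meta.tsv")
    report["n_features"] = len(act.pathway_ids)
    stage("activity")

    if config.ranker == "da":
        model = train(act.values.to_numpy().T, hidden=config.hidden,
                      corruption=config.corruption, lr=config.lr,
                      epochs=config.epochs, batch_size=config.batch_size,
                      seed=config.seed)
        save_model(model, out / "da_model")
        ranking = rank_by_da(model, act.pathway_ids)
    else:
        ranking = rank_by_ttest(act, labels)
    ranking.write(out / "ranking.tsv")
    stage("rank")

    cv = cross_validate(act, labels,
                        ranker=ranking if config.ranker == "da" else "ttest",
                        repeats=config.repeats, folds=config.folds,
                        seed=config.seed, max_n=config.max_n)
    cv.records.to_csv(out / "metrics.tsv", sep="\t", index=False)
    cv.consolidated.to_csv(out / "consolidated_features.tsv", sep="\t", index=False)
    report.update(mean_auc=cv.mean_auc, se_auc=cv.se_auc,
                  mean_accuracy=cv.mean_accuracy, se_accuracy=cv.se_accuracy,
                  n_consolidated=len(cv.consolidated))
    stage("evaluate")

    provenance = {
        "idrw_version": __version__,
        "numpy": np.__version__, "scipy": scipy.__version__,
        "pandas": pd.__version__, "sklearn": sklearn.__version__,
        "seed": config.seed, "config": asdict(config),
        "config_hash": config.config_hash(),
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
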