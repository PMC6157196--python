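"""Fully in-silico fixtures: pathways, base graph, two omics layers, labels.

The generator emulates the statistical shape of a paired bulk tumor cohort:
negative-binomial RNA-seq counts with log-normal baseline means, a continuous
methylation layer partially anti-correlated with expression through a shared
latent factor, a balanced good/poor phenotype, and a block-structured pathway
collection with a directed within-pathway interaction graph.  A chosen subset
of pathways is "planted" differentially active: their genes get an expression
fold change and a methylation shift in the poor group.  Everything is
reproducible from a single seed and the ground truth is returned alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .io import (EXPRESSION, GOOD, METHYLATION, POOR, OmicsMatrix, PathwayDB,
                 PhenotypeLabels)

log = logging.getLogger(__name__)

#: log-normal baseline mean parameters for NB counts (ln scale)
_BASE_MEAN_LN = np.log(100.0)
_BASE_MEAN_SD = 1.0
#: loading of the shared latent factor for anti-correlated genes
_ANTI_LOADING = 0.8
_ANTI_NOISE_SD = 0.6


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    planted_pathways: list[str]
    planted_genes: list[str]
    anti_genes: list[str]
    expr_lfc: float
    meth_shift: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_pathway_graph(n_genes: int = 1000, n_pathways: int = 50,
                           size_range: tuple[int, int] = (15, 25),
                           edge_density: float = 0.15,
                           inter_edge_rate: float = 0.02,
                           seed: int = 0) -> tuple[PathwayDB, nx.DiGraph]:
    """Block-structured pathways over a circular gene list plus a directed graph.

    Pathway k occupies a block of consecutive genes starting at
    ``k * (n_genes // n_pathways)``; blocks overlap when pathway sizes exceed
    the stride, mimicking shared genes between related pathways.  Directed
    edges are drawn within each pathway at ``edge_density``; on top, a sparse
    Poisson(``inter_edge_rate * n_genes``) number of random long-range edges
    connect arbitrary gene pairs.
    """
    if n_pathways < 1 or n_genes < n_pathways:
        raise ValueError("need at least one gene per pathway")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    stride = n_genes // n_pathways
    pw_width = len(str(n_pathways))
    pathways: dict[str, tuple[str, frozenset]] = {}
    graph = nx.DiGraph()
    graph.add_nodes_from(genes)
    for k in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        block = [genes[(k * stride + j) % n_genes] for j in range(size)]
        pid = f"PW{k + 1:0{pw_width}d}"
        pathways[pid] = (f"synthetic pathway {k + 1}", frozenset(block))
        if edge_density > 0:
            draw = rng.random((size, size)) < edge_density
            np.fill_diagonal(draw, False)
            for i, j in zip(*np.nonzero(draw)):
                graph.add_edge(block[i], block[j])
    if inter_edge_rate > 0:
        n_inter = int(rng.poisson(inter_edge_rate * n_genes))
        for _ in range(n_inter):
            u, v = rng.choice(n_genes, size=2, replace=False)
            graph.add_edge(genes[u], genes[v])
    log.info("generated %d pathways over %d genes; graph has %d edges",
             n_pathways, n_genes, graph.number_of_edges())
    return PathwayDB(pathways), graph


def generate_cohort(pathdb: PathwayDB, graph: nx.DiGraph, n_samples: int = 300,
                    planted: list[str] | int = 5, expr_lfc: float = 1.5,
                    meth_shift: float = 1.0, anti_frac: float = 0.3,
                    dispersion: float = 0.3, seed: int = 0):
    """Simulate paired expression/methylation profiles with planted pathways.

    Returns ``(expr, meth, labels, truth)``.  ``planted`` is either an explicit
    list of pathway ids or a count, in which case that many evenly spaced
    pathways are planted.  Poor-group samples have the planted genes' NB mean
    multiplied by ``2**expr_lfc`` and their methylation mean shifted by
    ``meth_shift``; a random ``anti_frac`` of all genes get methylation drawn
    anti-correlated with their own expression via a shared latent factor.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for pid in pathdb.ids for g in pathdb.members(pid)} | set(graph.nodes))
    n_genes = len(genes)
    if isinstance(planted, int):
        ids = pathdb.ids
        idx = np.linspace(0, len(ids) - 1, num=planted, dtype=int)
        planted = [ids[i] for i in sorted(set(idx))]
    unknown = [p for p in planted if p not in pathdb]
    if unknown:
        raise ValueError(f"planted pathways not in the database: {unknown}")
    planted_genes = sorted({g for pid in planted for g in pathdb.members(pid)})

    samples = [f"S{i + 1:0{len(str(n_samples))}d}" for i in range(n_samples)]
    group = np.where(rng.random(n_samples) < 0.5, POOR, GOOD).astype(object)
    if len(set(group)) == 1:  # pathological tiny-n draw; flip one sample
        group[0] = POOR if group[0] == GOOD else GOOD
    poor_mask = group == POOR
    labels = PhenotypeLabels(samples, group)

    base_mean = np.exp(rng.normal(_BASE_MEAN_LN, _BASE_MEAN_SD, size=n_genes))
    planted_mask = np.isin(genes, planted_genes)
    mu = np.tile(base_mean[:, None], (1, n_samples))
    mu[np.ix_(planted_mask, poor_mask)] *= 2.0 ** expr_lfc
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)
    expr = OmicsMatrix(EXPRESSION, pd.DataFrame(counts, index=genes, columns=samples),
                       "raw_counts")

    n_anti = int(round(anti_frac * n_genes))
    anti_idx = rng.choice(n_genes, size=n_anti, replace=False)
    anti_mask = np.zeros(n_genes, dtype=bool)
    anti_mask[anti_idx] = True
    meth = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    if n_anti:
        logc = np.log1p(counts[anti_mask])
        sd = logc.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        latent = (logc - logc.mean(axis=1, keepdims=True)) / sd
        meth[anti_mask] = (-_ANTI_LOADING * latent
                           + _ANTI_NOISE_SD * rng.normal(size=latent.shape))
    meth[np.ix_(planted_mask, poor_mask)] += meth_shift
    meth = OmicsMatrix(METHYLATION, pd.DataFrame(meth, index=genes, columns=samples),
                       "continuous")

    truth = GroundTruth(
        planted_pathways=list(planted),
        planted_genes=planted_genes,
        anti_genes=[genes[i] for i in sorted(anti_idx)],
        expr_lfc=expr_lfc, meth_shift=meth_shift, seed=seed,
        params={"n_samples": n_samples, "n_genes": n_genes,
                "anti_frac": anti_frac, "dispersion": dispersion})
    log.info("cohort: %d samples (%d poor / %d good), %d genes, %d planted pathways",
             n_samples, labels.n_poor, labels.n_good, n_genes, len(planted))
    return expr, meth, labels, truth


def inject_missing(meth: OmicsMatrix, rate: float, seed: int = 0) -> OmicsMatrix:
    """Set an i.i.d. fraction ``rate`` of methylation cells to missing (NaN)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    values = meth.values.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(values.shape) < rate
        arr = values.to_numpy(dtype=float, copy=True)
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return OmicsMatrix(meth.layer, values, meth.value_kind)
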