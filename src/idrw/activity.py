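"""Pathway activity inference from walk weights and differential evidence.

For a pathway P_j with differential member nodes g_1..g_n (members of the
pathway, present in the graph, with layer-specific p-value below alpha), the
per-sample activity is

    a(P_j) = sum_i Winf(g_i) * score(g_i) * z(g_i) / sqrt(sum_i Winf(g_i)^2)

where Winf is the stationary walk weight, score is the log2 fold change for
expression nodes and the sign of the t-statistic for methylation nodes, and
z(g_i) is the gene's z-scored profile in its own layer.  A gene differential
in both layers contributes two terms, one per node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstats import GeneStat, stat_lookup
from .graph import Node
from .io import EXPRESSION, METHYLATION, OmicsMatrix, PathwayDB
from .walk import NodeWeights

log = logging.getLogger(__name__)


@dataclass
class PathwayActivityMatrix:
    """Pathways x samples activity profile with per-pathway member metadata."""

    values: pd.DataFrame                      # pathways x samples
    members: dict[str, list[Node]] = field(default_factory=dict)
    meta: pd.DataFrame | None = None          # columns: n_total, n_de, n_dm

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path, meta_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="pathway_id")
        if meta_path is not None and self.meta is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="pathway_id")


def select_differential_members(pathway_genes, gene_stats, node_index,
                                alpha: float = 0.05) -> list[Node]:
    """Member nodes of a pathway that carry differential evidence.

    A node qualifies iff its gene belongs to the pathway, the (gene, layer)
    node exists in the graph, and its p-value is below ``alpha``.  Expression
    and methylation nodes of the same gene may both qualify.
    """
    if not isinstance(gene_stats, dict):
        gene_stats = stat_lookup(gene_stats)
    members = [node for node in node_index
               if node[0] in pathway_genes
               and node in gene_stats
               and gene_stats[node].p_value < alpha]
    return sorted(members)


def gene_score(stat: GeneStat) -> float:
    """Directional effect score: log2FC for expression, sign(t) for methylation."""
    if stat.layer == EXPRESSION:
        return float(stat.effect)
    return float(np.sign(stat.effect))


def activity(member_nodes: list[Node], winf: NodeWeights, gene_stats,
             zmatrices: dict[str, OmicsMatrix]) -> np.ndarray | None:
    """Per-sample activity of one pathway; None when all member weights vanish."""
    if not member_nodes:
        raise ValueError("pathway has no differential members")
    if not isinstance(gene_stats, dict):
        gene_stats = stat_lookup(gene_stats)
    node_index = {n: i for i, n in enumerate(winf.nodes)}
    samples = _common_samples(zmatrices)
    w = np.array([winf.values[node_index[n]] for n in member_nodes])
    denom = float(np.sqrt((w ** 2).sum()))
    if denom == 0:
        return None
    s = np.array([gene_score(gene_stats[n]) for n in member_nodes])
    Z = np.vstack([
        zmatrices[layer].values.loc[gene, samples].to_numpy()
        for gene, layer in member_nodes])
    return (w * s) @ Z / denom


def build_activity_matrix(pathdb: PathwayDB, gene_stats, winf: NodeWeights,
                          zmatrices: dict[str, OmicsMatrix],
                          alpha: float = 0.05) -> PathwayActivityMatrix:
    """Activity profile over all pathways with at least one differential member."""
    lookup = gene_stats if isinstance(gene_stats, dict) else stat_lookup(gene_stats)
    node_index = {n: i for i, n in enumerate(winf.nodes)}
    samples = _common_samples(zmatrices)
    rows, index, members_out, meta_rows = [], [], {}, []
    for pid in pathdb.ids:
        genes = pathdb.members(pid)
        members = select_differential_members(genes, lookup, node_index, alpha)
        if not members:
            continue
        a = activity(members, winf, lookup, zmatrices)
        if a is None:
            log.warning("pathway %s dropped: all member walk weights are zero", pid)
            continue
        rows.append(a)
        index.append(pid)
        members_out[pid] = members
        meta_rows.append({
            "n_total": len(genes),
            "n_de": sum(1 for _, layer in members if layer == EXPRESSION),
            "n_dm": sum(1 for _, layer in members if layer == METHYLATION),
        })
    if not rows:
        raise ValueError("no pathway has differential members; nothing to score")
    values = pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    meta = pd.DataFrame(meta_rows, index=index)
    log.info("activity matrix: %d of %d pathways retained, %d samples",
             len(index), len(pathdb), len(samples))
    return PathwayActivityMatrix(values, members_out, meta)


def _common_samples(zmatrices: dict[str, OmicsMatrix]) -> list[str]:
    mats = list(zmatrices.values())
    if not mats:
        raise ValueError("no z-scored matrices supplied")
    for m in mats:
        if m.value_kind != "zscored":
            raise ValueError(f"{m.layer} matrix must be z-scored")
    samples = mats[0].sample_ids
    for m in mats[1:]:
        if m.sample_ids != samples:
            raise ValueError("z-scored layers must share an identical sample order")
    return samples
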