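"""Two-layer integrated gene-gene graph and its transition matrix.

The graph has one node per (gene, layer) pair.  Within-layer edges replicate a
directed base gene-gene interaction graph (e.g. a KEGG-derived global graph)
restricted to the genes measured in that layer.  Cross-layer edges connect the
expression and methylation nodes of the same gene, either for every gene
present in both layers (``mode="all"``) or only when the two profiles are
significantly anti-correlated (``mode="anti"``), reflecting the repressive
action of promoter methylation on transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .io import EXPRESSION, METHYLATION, OmicsMatrix

log = logging.getLogger(__name__)

Node = tuple[str, str]  # (gene symbol, layer)

WITHIN_EXPR = "within_expr"
WITHIN_METH = "within_meth"
CROSS = "cross"

DANGLING_POLICIES = ("reinject", "uniform")


class GraphBuildError(ValueError):
    """The integrated graph could not be constructed from the inputs."""


@dataclass
class IntegratedGraph:
    """Directed graph over (gene, layer) nodes with a 0/1 sparse adjacency."""

    nodes: list[Node]
    node_index: dict[Node, int]
    adjacency: sparse.csr_matrix  # row = source, col = target

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def edges(self):
        coo = self.adjacency.tocoo()
        for i, j in zip(coo.row, coo.col):
            yield self.nodes[i], self.nodes[j]

    def edge_type(self, u: Node, v: Node) -> str:
        if u[1] != v[1]:
            return CROSS
        return WITHIN_EXPR if u[1] == EXPRESSION else WITHIN_METH

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(f"{u[0]}@{u[1]}", f"{v[0]}@{v[1]}", self.edge_type(u, v))
                for u, v in self.edges()]
        return pd.DataFrame(rows, columns=["source_node", "target_node", "edge_type"])

    def write_edges(self, path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TransitionMatrix:
    """Row-normalized adjacency: M[i, j] = 1/outdeg(i) for each edge i -> j."""

    M: sparse.csr_matrix
    dangling: np.ndarray  # boolean mask over node rows with no outgoing edge
    dangling_policy: str = "reinject"


def anticorrelation_test(x, y, alpha: float = 0.05):
    """Pearson correlation between two profiles with a significance gate.

    Returns ``(r, p, keep)`` where ``keep`` is True iff r < 0 and the two-sided
    p-value of the correlation t-test is below ``alpha``.  Constant input gives
    ``keep=False`` with a warning (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("anticorrelation_test: constant vector, correlation undefined")
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(r < 0 and p < alpha)


def build_integrated_graph(base_graph: nx.DiGraph, expr: OmicsMatrix,
                           meth: OmicsMatrix, mode: str = "all",
                           alpha: float = 0.05) -> IntegratedGraph:
    """Build the integrated two-layer graph from a base gene-gene graph.

    Parameters
    ----------
    base_graph : networkx.DiGraph
        Directed gene-gene interaction graph over gene symbols.
    expr, meth : OmicsMatrix
        The two omics layers; only genes present in the base graph get nodes.
    mode : {"all", "anti"}
        Cross-layer edge rule: every overlapping gene, or only genes whose
        expression and methylation profiles are significantly anti-correlated
        (Pearson r < 0, correlation-test p < ``alpha``).
    """
    if mode not in ("all", "anti"):
        raise ValueError(f"unknown mode {mode!r}")
    base_nodes = set(base_graph.nodes)
    genes_e = sorted(set(expr.gene_ids) & base_nodes)
    genes_m = sorted(set(meth.gene_ids) & base_nodes)
    if not genes_e or not genes_m:
        raise GraphBuildError("base graph shares no genes with one of the layers")

    nodes: list[Node] = [(g, EXPRESSION) for g in genes_e] + [(g, METHYLATION) for g in genes_m]
    node_index = {n: i for i, n in enumerate(nodes)}
    set_e, set_m = set(genes_e), set(genes_m)

    edges: set[tuple[int, int]] = set()
    for u, v in base_graph.edges:
        if u in set_e and v in set_e:
            edges.add((node_index[(u, EXPRESSION)], node_index[(v, EXPRESSION)]))
        if u in set_m and v in set_m:
            edges.add((node_index[(u, METHYLATION)], node_index[(v, METHYLATION)]))

    overlap = sorted(set_e & set_m)
    if mode == "all":
        linked = overlap
    else:
        common = [s for s in expr.sample_ids if s in set(meth.sample_ids)]
        if len(common) < 3:
            raise GraphBuildError("anti mode needs >= 3 shared samples")
        ev = expr.values[common]
        mv = meth.values[common]
        linked = []
        for g in overlap:
            _, _, keep = anticorrelation_test(ev.loc[g].to_numpy(),
                                              mv.loc[g].to_numpy(), alpha)
            if keep:
                linked.append(g)
        log.info("anti mode: %d of %d overlapping genes anti-correlated (alpha=%g)",
                 len(linked), len(overlap), alpha)
    for g in linked:
        ie, im = node_index[(g, EXPRESSION)], node_index[(g, METHYLATION)]
        edges.add((ie, im))
        edges.add((im, ie))

    n = len(nodes)
    if edges:
        rows, cols = zip(*sorted(edges))
        adjacency = sparse.csr_matrix(
            (np.ones(len(edges)), (rows, cols)), shape=(n, n))
    else:
        adjacency = sparse.csr_matrix((n, n))
    log.info("integrated graph: %d nodes (%d expr, %d meth), %d edges (mode=%s)",
             n, len(genes_e), len(genes_m), len(edges), mode)
    return IntegratedGraph(nodes, node_index, adjacency)


def build_layer_graph(base_graph: nx.DiGraph, matrix: OmicsMatrix) -> IntegratedGraph:
    """Single-layer graph (base edges restricted to one measured layer).

    Used by the concatenation baseline, where each omics layer is walked
    independently and no cross-layer edges exist.
    """
    base_nodes = set(base_graph.nodes)
    genes = sorted(set(matrix.gene_ids) & base_nodes)
    if not genes:
        raise GraphBuildError("base graph shares no genes with the layer")
    nodes: list[Node] = [(g, matrix.layer) for g in genes]
    node_index = {n: i for i, n in enumerate(nodes)}
    gene_set = set(genes)
    edges = {(node_index[(u, matrix.layer)], node_index[(v, matrix.layer)])
             for u, v in base_graph.edges if u in gene_set and v in gene_set}
    n = len(nodes)
    if edges:
        rows, cols = zip(*sorted(edges))
        adjacency = sparse.csr_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    else:
        adjacency = sparse.csr_matrix((n, n))
    return IntegratedGraph(nodes, node_index, adjacency)


def row_normalize(graph: IntegratedGraph,
                  dangling_policy: str = "reinject") -> TransitionMatrix:
    """Row-normalize the adjacency into a (sub)stochastic transition matrix.

    Rows without outgoing edges are left all-zero under the default
    ``"reinject"`` policy (the walk re-injects the lost mass through the
    restart vector); ``"uniform"`` links dangling rows to every node.
    """
    if dangling_policy not in DANGLING_POLICIES:
        raise ValueError(f"unknown dangling policy {dangling_policy!r}")
    outdeg = graph.out_degrees()
    dangling = outdeg == 0
    inv = np.zeros_like(outdeg, dtype=float)
    inv[~dangling] = 1.0 / outdeg[~dangling]
    M = sparse.diags(inv) @ graph.adjacency
    M = sparse.csr_matrix(M)
    if dangling_policy == "uniform" and dangling.any():
        M = sparse.lil_matrix(M)
        M[np.flatnonzero(dangling), :] = 1.0 / graph.n_nodes
        M = sparse.csr_matrix(M)
        dangling = np.zeros_like(dangling)
    return TransitionMatrix(M, dangling, dangling_policy)
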