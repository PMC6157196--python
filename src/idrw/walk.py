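"""Directed random walk with restart over the integrated graph.

Node weighting follows the standard three-step recipe: per-node evidence
v = -log(w_g + eps) from the differential p-value w_g, min-max scaling to
[0, 1] within each layer, and a single global L1 normalization producing the
restart distribution W0.  The walk iterates

    W_{t+1} = (1 - r) M^T W_t + r W0

until the L1 change drops below ``tol`` (default 1e-10).  Probability mass
that would be lost through dangling nodes (all-zero rows of M) is re-injected
through W0 each step, so the iterate stays a probability vector.  A direct
linear solve of the stationary system is provided as an exact cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstats import GeneStat, stat_lookup
from .graph import IntegratedGraph, Node, TransitionMatrix

log = logging.getLogger(__name__)

#: machine-epsilon guard inside the log so that p = 0 stays finite
EPS = 2.2e-16


class ConvergenceError(RuntimeError):
    """The power iteration failed to reach the tolerance within max_iter."""


@dataclass
class NodeWeights:
    """A weight vector over graph nodes (W0, W_t or the stationary W_inf)."""

    nodes: list[Node]
    values: np.ndarray
    stage: str  # {"initial", "iterate", "stationary"}
    n_iter: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.nodes):
            raise ValueError("values length does not match node list")
        if (self.values < -1e-12).any():
            raise ValueError("node weights must be non-negative")
        if self.stage in ("initial", "stationary"):
            total = self.values.sum()
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"{self.stage} weights must be L1-normalized (sum={total})")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=[f"{g}@{l}" for g, l in self.nodes])

    def __getitem__(self, node: Node) -> float:
        return float(self.values[self.nodes.index(node)])


def write_node_weights(weights: NodeWeights, path) -> None:
    weights.as_series().rename("weight").to_csv(path, sep="\t", index_label="node")


def initial_weights(gene_stats: list[GeneStat], graph: IntegratedGraph,
                    eps: float = EPS, minmax_scope: str = "layer") -> NodeWeights:
    """Build the restart distribution W0 from per-(gene, layer) p-values.

    Nodes without a statistic get p = 1 (no evidence).  The -log evidence is
    min-max scaled to [0, 1] within each layer (``minmax_scope="global"``
    scales over all nodes at once), then the whole vector is L1-normalized.
    A layer whose evidence is constant is set uniform within the layer.
    """
    if minmax_scope not in ("layer", "global"):
        raise ValueError(f"unknown minmax_scope {minmax_scope!r}")
    lookup = stat_lookup(gene_stats)
    p = np.ones(graph.n_nodes)
    n_missing = 0
    for i, node in enumerate(graph.nodes):
        stat = lookup.get(node)
        if stat is None:
            n_missing += 1
        else:
            p[i] = stat.p_value
    if n_missing:
        log.info("initial_weights: %d of %d nodes lack a statistic (p set to 1)",
                 n_missing, graph.n_nodes)
    v = -np.log(p + eps)

    layers = np.array([layer for _, layer in graph.nodes], dtype=object)
    scopes = [np.ones(len(v), dtype=bool)] if minmax_scope == "global" else [
        layers == layer for layer in dict.fromkeys(layers)]
    scaled = np.empty_like(v)
    for mask in scopes:
        lo, hi = v[mask].min(), v[mask].max()
        if hi == lo:
            log.warning("initial_weights: constant evidence in a scope, set uniform")
            scaled[mask] = 1.0
        else:
            scaled[mask] = (v[mask] - lo) / (hi - lo)
    total = scaled.sum()
    if total == 0:  # every node sat at its scope minimum; fall back to uniform
        scaled[:] = 1.0
        total = scaled.sum()
    return NodeWeights(graph.nodes, scaled / total, "initial")


def walk_iterates(transition: TransitionMatrix, w0: NodeWeights, r: float):
    """Yield successive walk iterates W_1, W_2, ... (W_0 itself is not yielded)."""
    if not 0 < r <= 1:
        raise ValueError("restart probability must be in (0, 1]")
    MT = transition.M.T.tocsr()
    dangling = transition.dangling
    w = w0.values
    while True:
        nxt = (1.0 - r) * (MT @ w) + r * w0.values
        lost = (1.0 - r) * float(w[dangling].sum())
        if lost:
            nxt = nxt + lost * w0.values
        yield nxt
        w = nxt


def random_walk(transition: TransitionMatrix, w0: NodeWeights, r: float = 0.7,
                tol: float = 1e-10, max_iter: int = 10_000) -> NodeWeights:
    """Power-iterate the restart walk to its stationary distribution W_inf."""
    if r == 1.0:
        return NodeWeights(w0.nodes, w0.values.copy(), "stationary", n_iter=0)
    prev = w0.values
    for it, w in enumerate(walk_iterates(transition, w0, r), start=1):
        residual = float(np.abs(w - prev).sum())
        if residual < tol:
            return NodeWeights(w0.nodes, w, "stationary", n_iter=it)
        prev = w
        if it >= max_iter:
            raise ConvergenceError(
                f"no convergence after {max_iter} iterations (L1 residual {residual:.3e})")


def stationary_solve(transition: TransitionMatrix, w0: NodeWeights,
                     r: float = 0.7) -> NodeWeights:
    """Solve the stationary system directly: (I - (1-r)M^T - (1-r) W0 d^T) W = r W0.

    The rank-one term folds the dangling-mass re-injection into the linear
    system, so the result matches the power iteration exactly.  Intended as an
    oracle for moderate graph sizes (dense solve).
    """
    if r == 1.0:
        return NodeWeights(w0.nodes, w0.values.copy(), "stationary", n_iter=0)
    n = len(w0.values)
    A = np.eye(n) - (1.0 - r) * transition.M.T.toarray()
    d = transition.dangling.astype(float)
    A -= (1.0 - r) * np.outer(w0.values, d)
    try:
        w = np.linalg.solve(A, r * w0.values)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by r > 0
        raise np.linalg.LinAlgError(f"stationary system singular: {exc}") from exc
    return NodeWeights(w0.nodes, w, "stationary")
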