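"""Per-gene differential statistics between survival groups.

Each gene in each omics layer gets a p-value (the gene weight w_g feeding the
random walk) and an effect score: the log2 fold change for expression counts,
the Welch t-statistic for methylation.  Expression counts are tested with a
negative-binomial Wald test (median-of-ratios size factors, method-of-moments
dispersion); externally computed results tables (e.g. from DESeq2) can be
loaded instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GOOD, POOR, OmicsMatrix, ParseError, PhenotypeLabels

log = logging.getLogger(__name__)

#: effect magnitude reported when group variances are zero but means differ
_DEGENERATE_T = 1e6


@dataclass(frozen=True)
class GeneStat:
    """Differential statistic for one (gene, layer) pair."""

    gene: str
    layer: str
    p_value: float
    effect: float  # log2 fold change (expression) or t-statistic (methylation)
    test: str      # {"nb_wald", "welch_t", "external"}


def stat_lookup(gene_stats: list[GeneStat]) -> dict[tuple[str, str], GeneStat]:
    """Index a stat list by (gene, layer)."""
    return {(s.gene, s.layer): s for s in gene_stats}


def _group_matrices(matrix: OmicsMatrix, labels: PhenotypeLabels):
    lookup = labels.group_of()
    unlabelled = [s for s in matrix.sample_ids if s not in lookup]
    if unlabelled:
        raise ValueError(f"samples without labels: {unlabelled[:5]}")
    groups = np.array([lookup[s] for s in matrix.sample_ids], dtype=object)
    good = matrix.values.to_numpy()[:, groups == GOOD]
    poor = matrix.values.to_numpy()[:, groups == POOR]
    if good.shape[1] < 2 or poor.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    return good, poor


def welch_t_test(matrix: OmicsMatrix, labels: PhenotypeLabels) -> list[GeneStat]:
    """Two-tailed Welch t-test per gene, poor vs good.

    Positive t means the gene is higher in the poor-survival group.  Genes whose
    values are constant in both groups get t=0, p=1 (no evidence either way).
    """
    good, poor = _group_matrices(matrix, labels)
    t, p = stats.ttest_ind(poor, good, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        diff = poor.mean(axis=1) - good.mean(axis=1)
        same = np.isclose(diff, 0.0)
        t[degenerate & same] = 0.0
        p[degenerate & same] = 1.0
        # zero variance but different means: evidence is overwhelming, not absent
        t[degenerate & ~same] = np.sign(diff[degenerate & ~same]) * _DEGENERATE_T
        p[degenerate & ~same] = 0.0
        log.warning("welch_t_test: %d zero-variance genes handled", int(degenerate.sum()))
    return [GeneStat(g, matrix.layer, float(pi), float(ti), "welch_t")
            for g, ti, pi in zip(matrix.gene_ids, t, p)]


# ---------------------------------------------------------------------------
# negative-binomial Wald test
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (DESeq-style).

    The ratio of each sample's counts to the per-gene geometric mean is taken
    over genes with all-positive counts; the per-sample median of those ratios
    is the size factor.  Falls back to relative column sums when no gene is
    positive everywhere.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        loggeo = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - loggeo, axis=0))
    else:
        colsum = counts.sum(axis=0)
        if (colsum == 0).any():
            raise ValueError("sample with zero total counts")
        sf = colsum / np.exp(np.mean(np.log(colsum)))
    return sf


def nb_wald_test(matrix: OmicsMatrix, labels: PhenotypeLabels,
                 dispersion_floor: float = 1e-8) -> list[GeneStat]:
    """Negative-binomial Wald test per gene, poor vs good.

    Group means of size-factor-normalized counts give the log2 fold change
    (poor over good); a per-gene method-of-moments dispersion (floored at
    ``dispersion_floor``) yields the Wald standard error, and the p-value is
    two-sided against a Student-t reference with n-2 degrees of freedom.
    All-zero genes are excluded with a warning.
    """
    counts = matrix.values.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    good, poor = _group_matrices(matrix, labels)
    lookup = labels.group_of()
    groups = np.array([lookup[s] for s in matrix.sample_ids], dtype=object)
    sf = size_factors(counts)
    sf_good, sf_poor = sf[groups == GOOD], sf[groups == POOR]

    nonzero = counts.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        log.warning("nb_wald_test: excluded %d all-zero genes", n_excluded)

    q = counts / sf  # normalized counts
    q_good_mat, q_poor_mat = q[:, groups == GOOD], q[:, groups == POOR]
    n1, n2 = q_good_mat.shape[1], q_poor_mat.shape[1]
    s_good, s_poor = sf_good.sum(), sf_poor.sum()
    s2_good, s2_poor = (sf_good ** 2).sum(), (sf_poor ** 2).sum()

    sum_good = counts[:, groups == GOOD].sum(axis=1)
    sum_poor = counts[:, groups == POOR].sum(axis=1)
    # continuity adjustment keeps the log defined when one group is all zero
    pseudo = (sum_good == 0) | (sum_poor == 0)
    sum_good = sum_good + 0.5 * pseudo
    sum_poor = sum_poor + 0.5 * pseudo
    q_good = sum_good / s_good
    q_poor = sum_poor / s_poor

    # method-of-moments dispersion from pooled within-group variance of q:
    # Var(q_j) ~= mu * E[1/s_j] + alpha * mu^2
    v = ((n1 - 1) * q_good_mat.var(axis=1, ddof=1)
         + (n2 - 1) * q_poor_mat.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    m = (n1 * q_good + n2 * q_poor) / (n1 + n2)
    mean_inv_sf = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m * mean_inv_sf) / m ** 2
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    var_ln_good = 1.0 / (q_good * s_good) + alpha * s2_good / s_good ** 2
    var_ln_poor = 1.0 / (q_poor * s_poor) + alpha * s2_poor / s_poor ** 2
    beta = np.log(q_poor) - np.log(q_good)
    se = np.sqrt(var_ln_good + var_ln_poor)
    wald = beta / se
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df=df)
    log2fc = beta / np.log(2.0)

    return [GeneStat(g, matrix.layer, float(pi), float(fi), "nb_wald")
            for g, fi, pi, keep in zip(matrix.gene_ids, log2fc, p, nonzero) if keep]


# ---------------------------------------------------------------------------
# external results tables
# ---------------------------------------------------------------------------

def load_external_stats(path, layer: str) -> list[GeneStat]:
    """Load a DESeq2-style results TSV with columns gene, log2FoldChange, pvalue."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2FoldChange", "pvalue"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    out: list[GeneStat] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        p, eff = getattr(row, "pvalue"), getattr(row, "log2FoldChange")
        if pd.isna(p) or pd.isna(eff):
            n_skipped += 1
            continue
        out.append(GeneStat(str(row.gene), layer, float(p), float(eff), "external"))
    if n_skipped:
        log.warning("%s: skipped %d rows with missing statistics", path, n_skipped)
    return out


def write_stats(gene_stats: list[GeneStat], path) -> None:
    pd.DataFrame({
        "gene": [s.gene for s in gene_stats],
        "log2FoldChange": [s.effect for s in gene_stats],
        "pvalue": [s.p_value for s in gene_stats],
    }).to_csv(path, sep="\t", index=False)
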