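"""Readers, writers and cohort preprocessing.

Input formats are deliberately plain: TSV matrices (genes x samples, header row
= sample ids), GMT gene sets, two-column TSV edge lists and a clinical table
(sample_id, vital_status, survival_days).  Preprocessing mirrors a standard
multi-omics survival workflow: low-expression filtering, per-patient median
imputation of missing methylation values, per-gene z-scoring, and a good/poor
survival split at a fixed follow-up threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EXPRESSION = "expression"
METHYLATION = "methylation"
LAYERS = (EXPRESSION, METHYLATION)

#: tokens treated as missing values in TSV matrices
NA_TOKENS = ("NA", "NaN", "")

GOOD = "good"
POOR = "poor"


class ParseError(ValueError):
    """A file violated its format contract."""


class CohortError(ValueError):
    """A cohort-level precondition failed (e.g. empty after filtering)."""


@dataclass
class OmicsMatrix:
    """One omics layer: a genes x samples matrix of real values.

    Parameters
    ----------
    layer : {"expression", "methylation"}
    values : pandas.DataFrame
        Genes as the index, samples as columns.  Missing values are NaN.
    value_kind : {"raw_counts", "continuous", "zscored"}
    """

    layer: str
    values: pd.DataFrame
    value_kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.value_kind not in ("raw_counts", "continuous", "zscored"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ParseError(f"duplicate gene ids in {self.layer} matrix: {sorted(set(dup))[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_samples(self, samples: list[str]) -> "OmicsMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from {self.layer} matrix: {missing[:5]}")
        return OmicsMatrix(self.layer, self.values[samples].copy(), self.value_kind)


@dataclass
class PhenotypeLabels:
    """Good/poor survival-group assignment, one group per sample."""

    sample_ids: list[str]
    group: np.ndarray  # array of "good"/"poor", parallel to sample_ids

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        if len(self.sample_ids) != len(self.group):
            raise ValueError("sample_ids and group length mismatch")
        bad = set(self.group) - {GOOD, POOR}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in labels")

    @property
    def n_good(self) -> int:
        return int(np.sum(self.group == GOOD))

    @property
    def n_poor(self) -> int:
        return int(np.sum(self.group == POOR))

    def binary(self) -> np.ndarray:
        """0/1 vector with poor = 1 (the event-like class)."""
        return (self.group == POOR).astype(int)

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.group))

    def subset(self, samples: list[str]) -> "PhenotypeLabels":
        lookup = self.group_of()
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"unlabelled samples: {missing[:5]}")
        return PhenotypeLabels(list(samples), np.array([lookup[s] for s in samples], dtype=object))


@dataclass
class PathwayDB:
    """Pathway id -> (description, member gene set)."""

    pathways: dict[str, tuple[str, frozenset]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __contains__(self, pid) -> bool:
        return pid in self.pathways

    @property
    def ids(self) -> list[str]:
        return list(self.pathways)

    def members(self, pid: str) -> frozenset:
        return self.pathways[pid][1]

    def description(self, pid: str) -> str:
        return self.pathways[pid][0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, layer: str, value_kind: str = "continuous",
                na_tokens=NA_TOKENS) -> OmicsMatrix:
    """Read a genes x samples TSV (first column gene symbols, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(na_tokens),
                     keep_default_na=False, dtype=str)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in header")
    df.index = df.index.astype(str).str.strip()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[g, s]!r} at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}")
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        log.info("%s: %d missing values", path, n_missing)
    return OmicsMatrix(layer, numeric.astype(float), value_kind)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_gmt(path) -> PathwayDB:
    """Read a GMT gene-set file (name, description, members; tab-separated)."""
    pathways: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            pid, desc = fields[0].strip(), fields[1]
            if pid in pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            members = [g.strip() for g in fields[2:]]
            dropped = sum(1 for g in members if not g)
            if dropped:
                log.warning("%s:%d: dropped %d empty gene tokens", path, lineno, dropped)
            members = frozenset(g for g in members if g)
            if not members:
                raise ParseError(f"{path}:{lineno}: pathway {pid!r} has no members")
            pathways[pid] = (desc, members)
    if not pathways:
        raise ParseError(f"{path}: empty GMT file")
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid in db.ids:
            fh.write("\t".join([pid, db.description(pid), *sorted(db.members(pid))]) + "\n")


def read_edge_list(path) -> nx.DiGraph:
    """Read a directed gene-gene edge list (TSV: source, target[, ignored])."""
    g = nx.DiGraph()
    n_self = n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: need >= 2 columns")
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: empty gene symbol")
            if u == v:
                n_self += 1
            n_lines += 1
            g.add_edge(u, v)
    if n_self:
        log.warning("%s: %d self-loop lines", path, n_self)
    log.info("%s: %d edge lines -> %d unique directed edges, %d genes",
             path, n_lines, g.number_of_edges(), g.number_of_nodes())
    return g


def write_edge_list(graph: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df


def write_labels(labels: PhenotypeLabels, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "group": labels.group}).to_csv(
        path, sep="\t", index=False)


def read_labels(path) -> PhenotypeLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ParseError(f"{path}: need columns sample_id, group")
    return PhenotypeLabels(list(df["sample_id"]), df["group"].to_numpy(dtype=object))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def derive_groups(clinical, threshold_days: int = 1095) -> PhenotypeLabels:
    """Split a clinical table into good (> threshold) / poor (<= threshold) groups.

    Rules: samples with missing or negative survival days are removed; patients
    still alive (vital_status == 1) with follow-up shorter than the threshold
    are removed (their class is unknowable); the remainder are split on
    survival days.
    """
    if not isinstance(clinical, pd.DataFrame):
        clinical = read_clinical(clinical)
    required = {"sample_id", "vital_status", "survival_days"}
    if not required <= set(clinical.columns):
        raise ParseError(f"clinical table needs columns {sorted(required)}")
    df = clinical.copy()
    df["survival_days"] = pd.to_numeric(df["survival_days"], errors="coerce")
    df["vital_status"] = pd.to_numeric(df["vital_status"], errors="coerce")
    n0 = len(df)
    df = df[df["survival_days"].notna() & (df["survival_days"] >= 0)]
    n_bad_days = n0 - len(df)
    alive = df["vital_status"] == 1
    censored_early = alive & (df["survival_days"] < threshold_days)
    df = df[~censored_early]
    if n_bad_days or int(censored_early.sum()):
        log.info("derive_groups: removed %d invalid-days and %d short-follow-up samples",
                 n_bad_days, int(censored_early.sum()))
    if df.empty:
        raise CohortError("no samples left after survival filtering")
    group = np.where(df["survival_days"] > threshold_days, GOOD, POOR)
    labels = PhenotypeLabels(list(df["sample_id"].astype(str)), group.astype(object))
    if labels.n_good == 0 or labels.n_poor == 0:
        log.warning("derive_groups: one survival group is empty (good=%d, poor=%d)",
                    labels.n_good, labels.n_poor)
    return labels


def filter_low_expression(matrix: OmicsMatrix) -> OmicsMatrix:
    """Drop genes whose expression is zero in more than half of the samples."""
    if matrix.layer != EXPRESSION:
        raise ValueError("filter_low_expression applies to the expression layer")
    values = matrix.values
    n_zero = (values == 0).sum(axis=1)
    keep = n_zero <= values.shape[1] / 2  # strict "more than half" removed
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_low_expression: removed %d of %d genes", n_drop, len(values))
    return OmicsMatrix(matrix.layer, values.loc[keep].copy(), matrix.value_kind)


def impute_median(matrix: OmicsMatrix, axis: str = "sample") -> OmicsMatrix:
    """Replace missing values by the median of the corresponding sample (column).

    ``axis="gene"`` uses the per-gene (row) median instead.
    """
    if axis not in ("sample", "gene"):
        raise ValueError("axis must be 'sample' or 'gene'")
    values = matrix.values.copy()
    mask = values.isna()
    n_missing = int(mask.to_numpy().sum())
    if n_missing == 0:
        return OmicsMatrix(matrix.layer, values, matrix.value_kind)
    if axis == "sample":
        fully_missing = mask.all(axis=0)
        if fully_missing.any():
            raise CohortError(
                f"samples entirely missing: {list(values.columns[fully_missing])[:5]}")
        values = values.fillna(values.median(axis=0, skipna=True), axis=0)
    else:
        fully_missing = mask.all(axis=1)
        if fully_missing.any():
            raise CohortError(
                f"genes entirely missing: {list(values.index[fully_missing])[:5]}")
        med = values.median(axis=1, skipna=True)
        values = values.T.fillna(med).T
    log.info("impute_median: imputed %d cells (%s-wise)", n_missing, axis)
    return OmicsMatrix(matrix.layer, values, matrix.value_kind)


def zscore(matrix: OmicsMatrix, ddof: int = 1) -> OmicsMatrix:
    """Standardize each gene to mean 0 / sd 1 across samples (sample sd, ddof=1)."""
    values = matrix.values
    if values.isna().to_numpy().any():
        raise ValueError("zscore requires a complete matrix; impute first")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    zero_var = sd == 0
    if zero_var.any():
        raise ValueError(
            f"zero-variance genes cannot be z-scored: {list(values.index[zero_var])[:5]}")
    z = values.sub(mean, axis=0).div(sd, axis=0)
    return OmicsMatrix(matrix.layer, z, "zscored")
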