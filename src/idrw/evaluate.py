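"""Feature ranking, greedy selection and cross-validated survival classification.

Pathway features are ranked either by a Welch t-test of their activities
between survival groups or by denoising-autoencoder weights.  Within each
training fold a greedy forward search walks the ranking and keeps a feature
only when it strictly improves an inner cross-validated AUC; the selected set
is evaluated with logistic regression on the held-out fold.  The whole 5-fold
procedure is repeated 10 times, and features appearing more than three times
across the 50 fold-level sets form the consolidated signature.

Note: gene weights and the random walk are computed once on the full cohort
(only the ranking and selection are fold-wise), so the reported AUC shares
the mild information leakage of the original protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .activity import PathwayActivityMatrix, select_differential_members
from .diffstats import stat_lookup
from .io import GOOD, POOR, EXPRESSION, METHYLATION, OmicsMatrix, PathwayDB, PhenotypeLabels
from .ranking import FeatureRanking, RankedFeature

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Fold-level metrics and selected feature sets from repeated k-fold CV."""

    records: pd.DataFrame            # columns: repeat, fold, auc, accuracy
    feature_sets: list[list[str]]    # one selected set per fold record
    consolidated: pd.DataFrame = field(default=None)  # pathway_id, count, frequency

    @property
    def mean_auc(self) -> float:
        return float(self.records["auc"].mean())

    @property
    def se_auc(self) -> float:
        return float(self.records["auc"].std(ddof=1) / np.sqrt(len(self.records)))

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def se_accuracy(self) -> float:
        return float(self.records["accuracy"].std(ddof=1) / np.sqrt(len(self.records)))


def _as_frame(activity) -> pd.DataFrame:
    if isinstance(activity, PathwayActivityMatrix):
        return activity.values
    return activity


def rank_by_ttest(activity, labels: PhenotypeLabels) -> FeatureRanking:
    """Rank pathways by the Welch t-test p-value of their activity rows."""
    df = _as_frame(activity)
    lookup = labels.group_of()
    groups = np.array([lookup[s] for s in df.columns], dtype=object)
    if (groups == GOOD).sum() < 2 or (groups == POOR).sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    poor = df.to_numpy()[:, groups == POOR]
    good = df.to_numpy()[:, groups == GOOD]
    _, p = stats.ttest_ind(poor, good, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    order = sorted(range(len(df)), key=lambda j: (p[j], df.index[j]))
    entries = [RankedFeature(df.index[j], float(p[j]), rank)
               for rank, j in enumerate(order, start=1)]
    return FeatureRanking(entries, "ttest")


def _fit_logistic(X: np.ndarray, y: np.ndarray, l2_C: float | None = None):
    # l2_C=None means unpenalized (C = inf); otherwise ridge with strength 1/C
    clf = LogisticRegression(C=np.inf if l2_C is None else l2_C,
                             solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        # unpenalized fits on separable folds hit the iteration cap harmlessly
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf

def _inner_cv_auc(X: np.ndarray, y: np.ndarray, folds: int, seed: int,
                  l2_C: float | None) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = _fit_logistic(X[tr], y[tr], l2_C)
        aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
    return float(np.mean(aucs))


def greedy_select(ranking: FeatureRanking, activity_train, labels_train,
                  max_n: int = 50, inner_folds: int = 3, seed: int = 0,
                  l2_C: float | None = None) -> list[str]:
    """Greedy forward search over the ranking, keeping strict AUC improvements.

    Features are tried in rank order (at most ``max_n`` of them); each is kept
    iff adding it strictly improves the inner ``inner_folds``-fold AUC on the
    training data.  The first-ranked feature is always kept (any AUC beats
    the empty model).
    """
    df = _as_frame(activity_train)
    y = labels_train.binary() if isinstance(labels_train, PhenotypeLabels) \
        else np.asarray(labels_train, dtype=int)
    selected: list[str] = []
    best = -np.inf
    for pid in ranking.ordered_ids[:max_n]:
        if pid not in df.index:
            continue
        trial = selected + [pid]
        auc = _inner_cv_auc(df.loc[trial].to_numpy().T, y, inner_folds, seed, l2_C)
        if auc > best:
            selected = trial
            best = auc
    return selected


def cross_validate(activity, labels: PhenotypeLabels, ranker="ttest",
                   repeats: int = 10, folds: int = 5, seed: int = 0,
                   max_n: int = 50, inner_folds: int = 3,
                   min_count: int = 4, l2_C: float | None = None) -> CVResult:
    """Repeated stratified k-fold evaluation of ranked-and-selected features.

    ``ranker`` is either ``"ttest"`` (re-ranked on each training fold) or a
    fixed :class:`FeatureRanking` (e.g. from the denoising autoencoder).
    Deterministic given ``seed``.
    """
    df = _as_frame(activity)
    labels = labels.subset(list(df.columns))
    y = labels.binary()
    if min(labels.n_good, labels.n_poor) < folds:
        raise ValueError("each class needs at least `folds` samples")
    rows, feature_sets = [], []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed * 100 + rep)
        for fold, (tr, te) in enumerate(skf.split(df.columns, y)):
            train_cols = [df.columns[i] for i in tr]
            test_cols = [df.columns[i] for i in te]
            if len(set(y[te])) < 2:
                raise ValueError("a fold lost one class; check stratification inputs")
            train_df = df[train_cols]
            if isinstance(ranker, FeatureRanking):
                fold_ranking = ranker
            elif ranker == "ttest":
                fold_ranking = rank_by_ttest(train_df, labels.subset(train_cols))
            else:
                raise ValueError(f"unknown ranker {ranker!r}")
            feats = greedy_select(fold_ranking, train_df, labels.subset(train_cols),
                                  max_n=max_n, inner_folds=inner_folds,
                                  seed=seed * 100 + rep, l2_C=l2_C)
            clf = _fit_logistic(train_df.loc[feats].to_numpy().T, y[tr], l2_C)
            Xte = df.loc[feats, test_cols].to_numpy().T
            auc = roc_auc_score(y[te], clf.decision_function(Xte))
            acc = accuracy_score(y[te], clf.predict(Xte))
            rows.append({"repeat": rep, "fold": fold, "auc": auc, "accuracy": acc,
                         "n_features": len(feats)})
            feature_sets.append(feats)
    records = pd.DataFrame(rows)
    consolidated = consolidate_features(feature_sets, min_count=min_count)
    return CVResult(records, feature_sets, consolidated)


def consolidate_features(feature_sets, min_count: int = 4) -> pd.DataFrame:
    """Features appearing at least ``min_count`` times across the fold sets.

    The default ``min_count=4`` implements the "more than 3 of 50" rule.
    Frequency is reported as "k/N" over the N fold-level sets.
    """
    if isinstance(feature_sets, CVResult):
        feature_sets = feature_sets.feature_sets
    n_sets = len(feature_sets)
    counts: dict[str, int] = {}
    for fs in feature_sets:
        for pid in set(fs):
            counts[pid] = counts.get(pid, 0) + 1
    kept = [(pid, c, f"{c}/{n_sets}") for pid, c in counts.items() if c >= min_count]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(kept, columns=["pathway_id", "count", "frequency"])


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def baseline_mean_median(zmatrices: dict[str, OmicsMatrix], pathdb: PathwayDB,
                         gene_stats, stat: str = "mean",
                         alpha: float = 0.05) -> PathwayActivityMatrix:
    """Pathway profile from the plain mean/median of significant member z-values.

    No walk weights and no effect directions: for each pathway, the per-sample
    mean (or median) of the z-scored values of its differential member nodes
    from both layers.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    lookup = gene_stats if isinstance(gene_stats, dict) else stat_lookup(gene_stats)
    node_index = {(g, m.layer): None for m in zmatrices.values() for g in m.gene_ids}
    samples = None
    rows, index, members_out = [], [], {}
    for pid in pathdb.ids:
        members = select_differential_members(pathdb.members(pid), lookup,
                                              node_index, alpha)
        members = [n for n in members if n[1] in zmatrices]
        if not members:
            continue
        Z = np.vstack([zmatrices[layer].values.loc[gene].to_numpy()
                       for gene, layer in members])
        rows.append(Z.mean(axis=0) if stat == "mean" else np.median(Z, axis=0))
        index.append(pid)
        members_out[pid] = members
        samples = zmatrices[members[0][1]].sample_ids
    if not rows:
        raise ValueError("no pathway has significant members")
    return PathwayActivityMatrix(pd.DataFrame(np.vstack(rows), index=index,
                                              columns=samples), members_out)


def baseline_drw_concat(expr_activity: PathwayActivityMatrix,
                        meth_activity: PathwayActivityMatrix) -> PathwayActivityMatrix:
    """Concatenate two single-layer pathway profiles (no cross-layer edges)."""
    a, b = expr_activity.values, meth_activity.values
    if set(a.columns) != set(b.columns):
        raise ValueError("sample sets differ between the two profiles")
    b = b[a.columns]
    a = a.rename(index=lambda pid: f"{pid}@{EXPRESSION}")
    b = b.rename(index=lambda pid: f"{pid}@{METHYLATION}")
    members = {f"{pid}@{EXPRESSION}": m for pid, m in expr_activity.members.items()}
    members.update({f"{pid}@{METHYLATION}": m for pid, m in meth_activity.members.items()})
    return PathwayActivityMatrix(pd.concat([a, b]), members)


def simpson_coefficient(set_a, set_b) -> float:
    """Overlap similarity |A intersect B| / min(|A|, |B|); 0 for empty sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def simpson_matrix(sets_a: dict[str, set], sets_b: dict[str, set]) -> pd.DataFrame:
    """Pairwise Simpson coefficients between two named collections of gene sets."""
    data = [[simpson_coefficient(sa, sb) for sb in sets_b.values()]
            for sa in sets_a.values()]
    return pd.DataFrame(data, index=list(sets_a), columns=list(sets_b))
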