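"""Feature ranking, greedy selection, cross-validation, baselines, Simpson."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import idrw
from idrw.evaluate import _fit_logistic

from conftest import make_labels, make_matrix


def planted_activity(rng, n_pathways=12, n_samples=60, shift=2.0, planted="PW01"):
    """Activity frame with one pathway shifted by `shift` SD in the poor group."""
    ids = [f"PW{j + 1:02d}" for j in range(n_pathways)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    labels = make_labels(["good"] * (n_samples // 2) + ["poor"] * (n_samples - n_samples // 2),
                         samples)
    values = rng.normal(size=(n_pathways, n_samples))
    values[ids.index(planted), labels.binary() == 1] += shift
    return pd.DataFrame(values, index=ids, columns=samples), labels


class TestRankByTtest:
    def test_identical_activity_ranked_last(self, rng):
        df, labels = planted_activity(rng)
        df.loc["PW12"] = 1.234  # constant row: no group difference at all
        ranking = idrw.rank_by_ttest(df, labels)
        assert ranking.ordered_ids[-1] == "PW12"
        assert ranking.entries[-1].score == pytest.approx(1.0)

    def test_planted_pathway_ranks_first(self, rng):
        df, labels = planted_activity(rng, shift=2.0)
        assert idrw.rank_by_ttest(df, labels).ordered_ids[0] == "PW01"

    def test_row_order_permutation_invariant(self, rng):
        df, labels = planted_activity(rng)
        shuffled = df.sample(frac=1, random_state=3)
        a = idrw.rank_by_ttest(df, labels)
        b = idrw.rank_by_ttest(shuffled, labels)
        assert a.ordered_ids == b.ordered_ids


class TestGreedySelect:
    def test_single_separating_feature_selected(self, rng):
        df, labels = planted_activity(rng, shift=6.0)
        ranking = idrw.rank_by_ttest(df, labels)
        selected = idrw.greedy_select(ranking, df, labels, max_n=6, seed=0)
        assert selected[0] == "PW01"

    def test_noise_feature_rejected_after_good_one(self, rng):
        df, labels = planted_activity(rng, n_pathways=2, shift=6.0)
        ranking = idrw.rank_by_ttest(df, labels)
        selected = idrw.greedy_select(ranking, df, labels, max_n=2, seed=0)
        assert selected == ["PW01"]  # PW02 is pure noise, AUC cannot improve on 1

    def test_max_n_one_keeps_top_ranked_only(self, rng):
        df, labels = planted_activity(rng)
        ranking = idrw.rank_by_ttest(df, labels)
        selected = idrw.greedy_select(ranking, df, labels, max_n=1, seed=0)
        assert selected == [ranking.ordered_ids[0]]


class TestCrossValidate:
    def test_null_features_give_chance_auc(self, rng):
        df, labels = planted_activity(rng, shift=0.0, n_samples=80)
        cv = idrw.cross_validate(df, labels, repeats=2, folds=4, seed=0, max_n=5)
        assert abs(cv.mean_auc - 0.5) < 0.1

    def test_separable_data_gives_auc_one(self, rng):
        df, labels = planted_activity(rng, shift=10.0)
        cv = idrw.cross_validate(df, labels, repeats=2, folds=3, seed=0, max_n=3)
        assert cv.mean_auc == pytest.approx(1.0)

    def test_same_seed_reproduces_result(self, rng):
        df, labels = planted_activity(rng, shift=1.0)
        a = idrw.cross_validate(df, labels, repeats=2, folds=3, seed=9, max_n=4)
        b = idrw.cross_validate(df, labels, repeats=2, folds=3, seed=9, max_n=4)
        assert a.records.equals(b.records)
        assert a.feature_sets == b.feature_sets

    def test_record_count_is_folds_times_repeats(self, rng):
        df, labels = planted_activity(rng)
        cv = idrw.cross_validate(df, labels, repeats=10, folds=5, seed=1, max_n=2)
        assert len(cv.records) == 50
        assert cv.records["auc"].between(0, 1).all()
        assert cv.records["accuracy"].between(0, 1).all()

    def test_fixed_da_ranking_is_used_verbatim(self, rng):
        df, labels = planted_activity(rng, shift=6.0)
        entries = [idrw.RankedFeature(pid, 0.0, k + 1)
                   for k, pid in enumerate(df.index)]
        fixed = idrw.FeatureRanking(entries, "da")
        cv = idrw.cross_validate(df, labels, ranker=fixed, repeats=1, folds=3,
                                 seed=0, max_n=1)
        assert all(fs == [df.index[0]] for fs in cv.feature_sets)

    def test_auc_matches_mann_whitney_oracle(self, rng):
        df, labels = planted_activity(rng, shift=1.5)
        y = labels.binary()
        X = df.to_numpy().T
        clf = _fit_logistic(X, y)
        scores = clf.decision_function(X)
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(y, scores)
        u = sps.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-10)


class TestConsolidate:
    def test_boundary_three_dropped_four_kept(self):
        sets = [["A", "B"]] * 4 + [["B"]] * 0 + [["C"]] * 3 + [[]] * 43
        out = idrw.consolidate_features(sets, min_count=4)
        assert list(out.pathway_id) == ["A", "B"]
        assert "C" not in set(out.pathway_id)

    def test_frequency_reported_over_fifty_sets(self):
        sets = [["DV"] if i < 10 else [] for i in range(50)]
        out = idrw.consolidate_features(sets)
        assert out.iloc[0].frequency == "10/50"

    def test_absent_feature_not_reported(self):
        out = idrw.consolidate_features([["A"]] * 50)
        assert set(out.pathway_id) == {"A"}

    @given(st.integers(1, 10))
    def test_raising_min_count_never_adds_features(self, k):
        rng = np.random.default_rng(0)
        sets = [[f"P{j}" for j in rng.choice(8, size=rng.integers(0, 5), replace=False)]
                for _ in range(50)]
        low = set(idrw.consolidate_features(sets, min_count=k).pathway_id)
        high = set(idrw.consolidate_features(sets, min_count=k + 1).pathway_id)
        assert high <= low


class TestBaselines:
    def test_single_member_mean_equals_gene_z(self, rng):
        z = make_matrix(rng.normal(size=(3, 5)), "expression",
                        genes=["A", "B", "C"], value_kind="zscored")
        stats = [idrw.GeneStat("A", "expression", 0.01, 1.0, "nb_wald"),
                 idrw.GeneStat("B", "expression", 0.9, 1.0, "nb_wald")]
        pathdb = idrw.PathwayDB({"P1": ("d", frozenset({"A", "B"}))})
        act = idrw.baseline_mean_median({"expression": z}, pathdb, stats, "mean")
        assert np.allclose(act.values.loc["P1"], z.values.loc["A"])

    @pytest.mark.parametrize("stat,expected", [("mean", 2.0), ("median", 2.0)])
    def test_two_member_mean_median(self, stat, expected):
        z = make_matrix(np.array([[1.0], [3.0]]), "expression",
                        genes=["A", "B"], value_kind="zscored")
        stats = [idrw.GeneStat(g, "expression", 0.01, 1.0, "nb_wald") for g in "AB"]
        pathdb = idrw.PathwayDB({"P1": ("d", frozenset({"A", "B"}))})
        act = idrw.baseline_mean_median({"expression": z}, pathdb, stats, stat)
        assert act.values.loc["P1"].iloc[0] == pytest.approx(expected)

    def test_five_member_matches_loop_oracle(self, rng):
        genes = list("ABCDE")
        z = make_matrix(rng.normal(size=(5, 7)), "expression", genes=genes,
                        value_kind="zscored")
        stats = [idrw.GeneStat(g, "expression", 0.01, 1.0, "nb_wald") for g in genes]
        pathdb = idrw.PathwayDB({"P1": ("d", frozenset(genes))})
        for stat, fn in (("mean", np.mean), ("median", np.median)):
            act = idrw.baseline_mean_median({"expression": z}, pathdb, stats, stat)
            for j in range(7):
                assert act.values.loc["P1"].iloc[j] == pytest.approx(
                    fn(z.values.to_numpy()[:, j]))

    def test_concat_stacks_rows_with_layer_suffix(self, rng):
        a = idrw.PathwayActivityMatrix(pd.DataFrame(
            rng.normal(size=(10, 4)), index=[f"P{i}" for i in range(10)],
            columns=list("wxyz")))
        b = idrw.PathwayActivityMatrix(pd.DataFrame(
            rng.normal(size=(8, 4)), index=[f"P{i}" for i in range(8)],
            columns=list("zyxw")))
        cat = idrw.baseline_drw_concat(a, b)
        assert len(cat.pathway_ids) == 18
        assert len(set(cat.pathway_ids)) == 18  # suffixes keep ids unique
        # columns align on sample id, not position
        assert np.allclose(cat.values.loc["P0@methylation"].to_numpy(),
                           b.values.loc["P0", list("wxyz")].to_numpy())

    def test_concat_sample_mismatch_raises(self, rng):
        a = idrw.PathwayActivityMatrix(pd.DataFrame(rng.normal(size=(2, 3)),
                                                    index=["P1", "P2"],
                                                    columns=list("abc")))
        b = idrw.PathwayActivityMatrix(pd.DataFrame(rng.normal(size=(2, 3)),
                                                    index=["P1", "P2"],
                                                    columns=list("abd")))
        with pytest.raises(ValueError, match="sample sets"):
            idrw.baseline_drw_concat(a, b)


class TestSimpson:
    @pytest.mark.parametrize("a,b,expected", [
        ({"a", "b", "c"}, {"b", "c", "d", "e"}, 2 / 3),
        ({"a"}, {"a", "b", "c"}, 1.0),       # subset
        ({"a", "b"}, {"c", "d"}, 0.0),       # disjoint
        (set(), {"a"}, 0.0),                 # empty set convention
    ])
    def test_definition(self, a, b, expected):
        assert idrw.simpson_coefficient(a, b) == pytest.approx(expected)

    @given(st.sets(st.integers(0, 5)), st.sets(st.integers(0, 5)))
    def test_symmetric_and_bounded(self, a, b):
        s = idrw.simpson_coefficient(a, b)
        assert 0.0 <= s <= 1.0
        assert s == idrw.simpson_coefficient(b, a)

    def test_matrix_layout(self):
        m = idrw.simpson_matrix({"x": {1, 2}}, {"u": {2}, "v": {3}})
        assert m.shape == (1, 2)
        assert m.loc["x", "u"] == 1.0 and m.loc["x", "v"] == 0.0
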