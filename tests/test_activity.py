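"""Pathway-activity algebra and member selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import idrw

from conftest import make_matrix


def stat(gene, layer, p, effect):
    return idrw.GeneStat(gene, layer, p, effect, "welch_t")


def zmat(values, layer, genes):
    return make_matrix(values, layer, genes=genes, value_kind="zscored")


def weights(nodes, values):
    v = np.asarray(values, dtype=float)
    return idrw.NodeWeights(list(nodes), v / v.sum(), "stationary")


class TestSelectMembers:
    def test_layer_specific_alpha_gate(self):
        node_index = {("A", "expression"): 0, ("A", "methylation"): 1,
                      ("B", "expression"): 2}
        stats = [stat("A", "expression", 0.01, 1.0),
                 stat("A", "methylation", 0.20, -1.0),
                 stat("B", "expression", 0.30, 0.5)]
        members = idrw.select_differential_members({"A", "B"}, stats, node_index)
        assert members == [("A", "expression")]

    def test_no_significant_members_gives_empty(self):
        node_index = {("A", "expression"): 0}
        members = idrw.select_differential_members(
            {"A"}, [stat("A", "expression", 0.5, 1.0)], node_index)
        assert members == []

    def test_matches_triple_filter_oracle(self, rng):
        genes = [f"G{i}" for i in range(30)]
        in_graph = set(rng.choice(genes, size=20, replace=False))
        node_index = {}
        for g in genes:
            if g in in_graph:
                node_index[(g, "expression")] = len(node_index)
                if rng.random() < 0.5:
                    node_index[(g, "methylation")] = len(node_index)
        stats = [stat(g, layer, float(rng.random()), 1.0)
                 for (g, layer) in node_index]
        pathway = set(rng.choice(genes, size=15, replace=False))
        got = idrw.select_differential_members(pathway, stats, node_index, alpha=0.4)
        lookup = idrw.stat_lookup(stats)
        expected = sorted(n for n in node_index
                          if n[0] in pathway and n in lookup
                          and lookup[n].p_value < 0.4)
        assert got == expected


class TestGeneScore:
    @pytest.mark.parametrize("layer,effect,expected", [
        ("expression", 1.7, 1.7),
        ("methylation", -3.2, -1.0),
        ("methylation", 0.0, 0.0),
        ("methylation", 2.5, 1.0),
    ])
    def test_score_convention(self, layer, effect, expected):
        assert idrw.gene_score(stat("A", layer, 0.01, effect)) == expected


class TestActivity:
    def setup_method(self):
        self.nodes = [("A", "expression"), ("B", "expression"), ("B", "methylation")]
        self.stats = [stat("A", "expression", 0.01, 2.0),
                      stat("B", "expression", 0.02, -1.5),
                      stat("B", "methylation", 0.03, 3.0)]
        rng = np.random.default_rng(5)
        self.z = {
            "expression": zmat(rng.normal(size=(2, 4)), "expression", ["A", "B"]),
            "methylation": zmat(rng.normal(size=(1, 4)), "methylation", ["B"]),
        }

    def test_single_member_reduces_to_score_times_z(self):
        w = weights(self.nodes, [0.4, 0.3, 0.3])
        a = idrw.activity([("A", "expression")], w, self.stats, self.z)
        assert np.allclose(a, 2.0 * self.z["expression"].values.loc["A"].to_numpy())

    def test_matches_direct_summation_oracle(self):
        w = weights(self.nodes, [0.5, 0.2, 0.3])
        members = list(self.nodes)
        a = idrw.activity(members, w, self.stats, self.z)
        scores = [2.0, -1.5, 1.0]
        wv = w.values
        for s_idx in range(4):
            num = (wv[0] * scores[0] * self.z["expression"].values.loc["A"].iloc[s_idx]
                   + wv[1] * scores[1] * self.z["expression"].values.loc["B"].iloc[s_idx]
                   + wv[2] * scores[2] * self.z["methylation"].values.loc["B"].iloc[s_idx])
            expected = num / np.sqrt((wv ** 2).sum())
            assert a[s_idx] == pytest.approx(expected)

    @given(st.floats(0.1, 100.0))
    def test_degree_zero_homogeneity_in_walk_weights(self, c):
        base = np.array([0.5, 0.2, 0.3])
        w1 = idrw.NodeWeights(self.nodes, base, "iterate")
        w2 = idrw.NodeWeights(self.nodes, c * base, "iterate")
        members = list(self.nodes)
        a1 = idrw.activity(members, w1, self.stats, self.z)
        a2 = idrw.activity(members, w2, self.stats, self.z)
        assert np.allclose(a1, a2, rtol=1e-9)

    def test_linearity_in_z(self, rng):
        w = weights(self.nodes, [0.5, 0.2, 0.3])
        members = list(self.nodes)

        def act(ze, zm):
            z = {"expression": zmat(ze, "expression", ["A", "B"]),
                 "methylation": zmat(zm, "methylation", ["B"])}
            return idrw.activity(members, w, self.stats, z)

        ze1, ze2 = rng.normal(size=(2, 2, 4))
        zm1, zm2 = rng.normal(size=(2, 1, 4))
        assert np.allclose(act(ze1 + ze2, zm1 + zm2),
                           act(ze1, zm1) + act(ze2, zm2), atol=1e-10)

    def test_score_sign_flip_negates_activity(self):
        w = weights(self.nodes, [0.5, 0.2, 0.3])
        members = list(self.nodes)
        flipped = [idrw.GeneStat(s.gene, s.layer, s.p_value, -s.effect, s.test)
                   for s in self.stats]
        a = idrw.activity(members, w, self.stats, self.z)
        b = idrw.activity(members, w, flipped, self.z)
        assert np.allclose(a, -b)

    def test_all_zero_weights_returns_none(self):
        w = idrw.NodeWeights(self.nodes, np.array([1.0, 0.0, 0.0]), "stationary")
        out = idrw.activity([("B", "expression")], w, self.stats, self.z)
        assert out is None


class TestBuildActivityMatrix:
    def test_pathway_without_members_dropped(self, small_pipeline):
        act = small_pipeline["activity"]
        pathdb = small_pipeline["pathdb"]
        assert set(act.pathway_ids) <= set(pathdb.ids)
        assert (act.meta[["n_de", "n_dm"]].sum(axis=1) >= 1).all()

    def test_composition_matches_per_pathway_ops(self, small_pipeline):
        sp = small_pipeline
        act = sp["activity"]
        lookup = idrw.stat_lookup(sp["stats"])
        node_index = sp["graph"].node_index
        for pid in act.pathway_ids[:3]:
            members = idrw.select_differential_members(
                sp["pathdb"].members(pid), lookup, node_index)
            a = idrw.activity(members, sp["winf"], lookup, sp["zmats"])
            assert np.allclose(act.values.loc[pid].to_numpy(), a)

    def test_sample_permutation_permutes_columns(self, small_pipeline):
        sp = small_pipeline
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(sp["activity"].sample_ids))
        zperm = {layer: idrw.OmicsMatrix(layer, m.values[perm], "zscored")
                 for layer, m in sp["zmats"].items()}
        act2 = idrw.build_activity_matrix(sp["pathdb"], sp["stats"], sp["winf"], zperm)
        assert act2.sample_ids == perm
        assert np.allclose(act2.values.to_numpy(),
                           sp["activity"].values[perm].to_numpy())

    def test_member_counts_split_by_layer(self, small_pipeline):
        act = small_pipeline["activity"]
        for pid, members in act.members.items():
            n_de = sum(1 for _, layer in members if layer == "expression")
            n_dm = sum(1 for _, layer in members if layer == "methylation")
            assert act.meta.loc[pid, "n_de"] == n_de
            assert act.meta.loc[pid, "n_dm"] == n_dm

    def test_no_surviving_pathway_raises(self):
        node_index = {("A", "expression"): 0}
        pathdb = idrw.PathwayDB({"P1": ("d", frozenset({"A"}))})
        w = idrw.NodeWeights([("A", "expression")], np.array([1.0]), "stationary")
        z = {"expression": zmat(np.zeros((1, 4)), "expression", ["A"])}
        with pytest.raises(ValueError, match="no pathway"):
            idrw.build_activity_matrix(pathdb, [stat("A", "expression", 0.9, 1.0)],
                                       w, z)
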