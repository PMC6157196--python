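"""Denoising-autoencoder feature ranking and overlap with the t-test ranking.

Trains a single-hidden-layer tied-weight denoising autoencoder on the
pathway-activity profile (samples as instances, pathways as features) and
ranks pathways by the mean encoder weight of their input node.  The Simpson
coefficient then measures how much the differential-gene content of the
DA-selected pathways overlaps the t-test-selected ones.
"""

import idrw

pathdb, base = idrw.generate_pathway_graph(n_genes=400, n_pathways=20, seed=42)
expr, meth, labels, truth = idrw.generate_cohort(
    pathdb, base, n_samples=120, planted=2, expr_lfc=1.5, meth_shift=1.0, seed=42)
stats = idrw.nb_wald_test(expr, labels) + idrw.welch_t_test(meth, labels)
graph = idrw.build_integrated_graph(base, expr, meth)
winf = idrw.random_walk(idrw.row_normalize(graph), idrw.initial_weights(stats, graph))
zmats = {"expression": idrw.zscore(expr), "methylation": idrw.zscore(meth)}
act = idrw.build_activity_matrix(pathdb, stats, winf, zmats)

model = idrw.train(act.values.to_numpy().T, hidden=50, corruption=0.1,
                   lr=0.01, epochs=300, batch_size=32, seed=0)
print(f"DA trained: {model.n_hidden} hidden units, "
      f"loss {model.loss_trace[0]:.3f} -> {model.loss_trace[-1]:.3f}")

da_ranking = idrw.rank_by_da(model, act.pathway_ids)
tt_ranking = idrw.rank_by_ttest(act, labels)
print("top-5 by DA weight vs by t-test:")
for a, b in zip(da_ranking.entries[:5], tt_ranking.entries[:5]):
    print(f"  {a.pathway_id} (|mean w| = {abs(a.score):.4f})   "
          f"{b.pathway_id} (p = {b.score:.2g})")

sig = {s.gene for s in stats if s.p_value < 0.05}
top_da = da_ranking.ordered_ids[:5]
top_tt = tt_ranking.ordered_ids[:5]
sets_da = {p: set(pathdb.members(p)) & sig for p in top_da}
sets_tt = {p: set(pathdb.members(p)) & sig for p in top_tt}
m = idrw.simpson_matrix(sets_da, sets_tt)
print("\nSimpson overlap of differential genes (DA rows x t-test columns):")
print(m.round(2).to_string())
print("\n1.0 means one selected gene set is contained in the other; "
      "0 means the two rankings picked disjoint biology.")
print("Note: DA scoring is unsupervised (reconstruction-driven), so its top "
      "features need not be the most group-separating ones - the two rankings "
      "answer different questions.")
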