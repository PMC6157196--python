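# idrw

Integrative pathway-activity inference from paired gene-expression and
DNA-methylation profiles, via a directed random walk with restart on a
two-layer gene-gene graph.

## The problem

Pathway-based survival prediction summarizes a tumor's omics profile into one
activity value per pathway per patient, then classifies patients (e.g. good
vs poor survival) from those activities. Methods that treat a pathway as a
bag of genes ignore both the topology of the gene network (hub genes matter
more) and the interplay between omics layers — promoter methylation
typically represses transcription of its own gene. `idrw` addresses both at
once: expression and methylation each contribute a full copy of a directed
gene-gene interaction graph, the two copies are linked by cross-layer edges
between the nodes of the same gene (optionally only where the two profiles
are significantly anti-correlated), and a random walk with restart
distributes differential-evidence mass over this integrated graph.

## The model

Each (gene, layer) node carries a p-value `w_g` — from a negative-binomial
Wald test on expression counts, or a Welch t-test on methylation — turned
into a restart distribution

    W0  ∝  minmax_per_layer( −log(w_g + ε) ),        ε = 2.2e−16,

L1-normalized, and iterated to stationarity with restart probability r = 0.7:

    W_{t+1} = (1 − r) Mᵀ W_t + r W0,      stop when |W_{t+1} − W_t|₁ < 1e−10,

where M is the row-normalized adjacency of the integrated graph. The
stationary weights W∞ score each node's topological importance weighted by
differential evidence. For a pathway P with differential member nodes
g₁…gₙ (p < 0.05), the per-sample activity is

    a(P) = Σᵢ W∞(gᵢ) · score(gᵢ) · z(gᵢ)  /  sqrt(Σᵢ W∞(gᵢ)²),

with `score` = log2 fold change (expression) or sign of the t-statistic
(methylation) and `z` the gene's z-scored profile in its own layer. Pathway
features are ranked by a Welch t-test of their activities or by the mean
encoder weights of a single-hidden-layer tied-weight denoising autoencoder
trained on the activity profile, and evaluated with greedy forward selection
plus logistic regression in stratified 5-fold cross-validation repeated 10
times; features selected in more than 3 of the 50 folds form the
consolidated signature. See `docs/methods.md` for every assumption and
default.

The package is aimed at computational biologists who have gene-level
expression counts, gene-level methylation values, survival labels, a
directed gene-gene edge list and a GMT pathway collection — or who want to
study the method itself on fully synthetic cohorts with known ground truth.

## Worked example

`examples/` contains one narrative script per capability. From the
repository root:

```sh
python examples/01_simulate_and_walk.py
```

simulates a 400-gene, 120-sample cohort with two planted differentially
active pathways and prints:

```
cohort: 400 genes x 120 samples (58 good / 62 poor); planted: ['PW01', 'PW20']
integrated graph: 800 nodes, 3318 directed edges
walk converged in 17 iterations; sum(W_inf) = 1.000000000000
L1 gap to the direct linear solve: 2.41e-11
top-10 walk-weighted nodes (gene@layer, weight, planted?):
  G388@expression   0.01724  True
  G381@expression   0.01603  True
  G388@methylation  0.01553  True
  ...
```

The walk conserves probability mass, matches the exact linear-solve oracle
to ~1e-11, and concentrates weight on planted genes in both layers.
`examples/03_rank_and_classify.py` continues to ranking and evaluation:

```
full-cohort t-test ranking (top 5):
  rank 1: PW20  p = 3.41e-68 <- planted
  rank 2: PW01  p = 3.46e-55 <- planted
  ...
mean AUC = 1.000 (SE 0.000), mean accuracy = 1.000 over 50 folds
consolidated features (> 3 of 50 folds):
pathway_id  count frequency
      PW20     50     50/50
```

Both planted pathways head the ranking; a single consolidated feature
(selected in all 50 folds) classifies this strongly-planted cohort
perfectly. `02_pathway_activity.py` shows the activity algebra and
per-pathway member counts; `04_autoencoder_ranking.py` trains the denoising
autoencoder and compares its (unsupervised, reconstruction-driven) ranking
with the t-test's via Simpson overlap.

The same pipeline runs from the shell on TSV/GMT inputs:

```sh
idrw simulate --n-genes 1000 --n-pathways 50 --seed 1 --out cohort/
idrw run-all --expr cohort/expression.tsv --meth cohort/methylation.tsv \
    --clinical cohort/clinical.tsv --graph cohort/graph.tsv \
    --gmt cohort/pathways.gmt --mode idrw --ranker ttest --out run/
```

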