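# Methods

`idrw` turns paired gene-expression and DNA-methylation profiles into a single
pathway-activity matrix by running a random walk with restart over an
integrated two-layer gene-gene graph, then ranks and evaluates pathway
features for survival-group classification. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## Cohort preprocessing

Samples are labelled *good* (survival > 3 years = 1095 days) or *poor*
(≤ 3 years); patients still alive with follow-up shorter than the threshold
are removed, because their class is unknowable. Samples with missing or
negative survival days are dropped. Expression genes with zeros in more than
half the samples (strictly more) are removed. Missing methylation values are
imputed with the median of the corresponding *patient* (column); a row-wise
variant exists (`impute_median(..., axis="gene")`) but the per-patient
reading matches the intended preprocessing. Both matrices are z-scored per
gene with the sample (n−1) standard-deviation convention. `ddof` is
configurable; switching conventions rescales every z-profile by the same
constant, so rankings and classification are unchanged and only the absolute
activity scale moves. Z-scoring happens after cohort filtering, on the
labelled samples only.

## Per-gene differential statistics

Each (gene, layer) node needs a p-value `w_g` and an effect score.

* **Methylation**: two-tailed Welch t-test, poor vs good. Effect = the
  t-statistic; only its sign enters the activity score.
* **Expression counts**: a negative-binomial Wald test written for this
  package: median-of-ratios size factors; a per-gene method-of-moments
  dispersion from the pooled within-group variance of normalized counts,
  floored at 1e-8; group means estimated as (group count sum)/(group size
  factor sum); Wald statistic on the log mean ratio with a delta-method
  standard error `Var(ln q̂) = 1/(q̂·S) + α·Σs²/S²`. P-values use a
  Student-t reference with n−2 degrees of freedom rather than the normal:
  at cohort sizes of tens of samples per group this keeps the null
  rejection rate at the nominal 5% (verified by simulation in the test
  suite). The effect is the log2 fold change, poor over good (the direction
  convention is documented here and fixed throughout). When one group's
  count sum is zero, 0.5 is added to both sums to keep the log defined.
  Externally computed DESeq2-style result tables can be injected through
  `load_external_stats` and are treated identically downstream.
* No multiple-testing correction is applied anywhere: the procedure uses raw
  p < 0.05 throughout, deliberately.

## The integrated graph

Nodes are (gene, layer) pairs. Within-layer edges replicate a directed base
gene-gene interaction graph restricted to the genes measured in that layer;
the base graph is consumed as an edge-list file (for real analyses, a
KEGG-derived global pathway graph). Cross-layer edges are bi-directional and
connect the expression and methylation nodes of the same gene — either for
every overlapping gene (`mode="all"`) or only when the two profiles are
significantly anti-correlated (`mode="anti"`: Pearson r < 0 and two-sided
correlation-test p < 0.05), reflecting methylation's repressive action.
In both modes the anti-correlation decision gates the gene pair, not the
edge direction. Genes measured in only one layer contribute one node.

## Random walk with restart

Initial weights: `v = −ln(w_g + ε)` with ε = 2.2e−16 (nodes without a
statistic get p = 1); min-max scaling to [0, 1] *within each layer* (so the
two layers' evidence scales cannot drown each other; a global min-max is
available via `minmax_scope`); then one global L1 normalization gives W₀.
The log base is immaterial — min-max scaling cancels any positive constant
factor, which a test proves.

The walk iterates `W_{t+1} = (1−r)·Mᵀ·W_t + r·W₀` with restart probability
r = 0.7 (the reference value; performance is insensitive to it) and M the
row-normalized adjacency. Convergence is declared when the L1 change drops
below 1e-10; the L1 norm is a choice (the update contracts in L1 with factor
(1−r), so convergence is geometric and reached in a few dozen iterations).
`max_iter` defaults to 10,000 and is never approached in practice.

**Dangling nodes** (no outgoing edges) would leak probability mass. Rows of
M for dangling nodes are left all-zero and the lost mass `(1−r)·Σ_dangling
W_t` is re-injected through W₀ each step, which keeps ΣW_t = 1 exactly and
has a clean closed form: the stationary vector solves
`(I − (1−r)Mᵀ − (1−r)·W₀·dᵀ)·W = r·W₀`, implemented as `stationary_solve`
and used as the exact oracle against the power iteration. A `"uniform"`
dangling policy (link to every node) is available but not the default.

## Pathway activity

For pathway P with differential member nodes g₁…gₙ (pathway members,
present in the graph, with `w_g` < 0.05 in their layer — a gene differential
in both layers contributes two nodes):

    a(P) = Σᵢ W∞(gᵢ) · score(gᵢ) · z(gᵢ) / sqrt(Σᵢ W∞(gᵢ)²)

where `score` is the log2 fold change for expression nodes and sign(t) for
methylation nodes, and `z(gᵢ)` is the gene's z-scored profile *in its own
layer*. The denominator uses only the member nodes' walk weights, exactly as
written, which makes the activity homogeneous of degree zero in W∞, linear
in z, and antisymmetric under flipping all effect signs — all tested
exactly. Pathways without differential members, or whose members all carry
zero walk weight, are dropped.

## Denoising-autoencoder feature ranking

A single-hidden-layer tied-weight autoencoder: `y = σ(W·x̃ + b)`,
`z = σ(Wᵀ·y + b_dec)`, trained to minimize `‖x − z‖²/2` of the clean input
from a masking-corrupted x̃ (each coordinate zeroed independently). Squared
error is used instead of cross-entropy because activities are not confined
to [0, 1]; the inputs are used as-is, without rescaling. The decoder bias is
an independent length-d vector (the tied-transpose notation for the bias is
dimensionally ambiguous; an independent bias is the standard resolution).
Since a sigmoid decoder cannot reconstruct values outside (0, 1), a
`decoder="linear"` option exists for users who care about reconstruction;
the sigmoid form remains the default for fidelity to the reference
formulation, and for ranking purposes the distinction is minor.

Hyperparameters (all configurable): 200 hidden units (the reference value;
the selected features are insensitive between 50 and 200), corruption rate
0.1 (unspecified upstream; a light masking level typical for DA feature
selection), plain minibatch SGD with learning rate 0.01, 500 epochs, batch
32, Glorot-uniform initialization, all driven by one seeded generator so
training is bitwise reproducible. Feature j's score is the mean of encoder
weight column j; ranking is by descending |score| with the signed score
reported (the magnitude reading of "mean weight"; a signed ordering is
available via `signed=True`). Ties break lexicographically. Analytic
gradients are verified against central differences to 1e-5 in the tests.
Note the DA criterion is unsupervised: it ranks features by their role in
reconstruction, not by group separation, so its top features can differ
sharply from the t-test's.

## Feature selection and evaluation

Pathways are ranked by a Welch t-test of their activity rows (ascending
p-value, lexicographic ties) or by the DA scores. Evaluation is stratified
5-fold cross-validation repeated 10 times (stratification is a choice; the
reference protocol only says "divided into five folds"): per training fold
the t-test ranking is recomputed (a fixed DA ranking is used verbatim), a
greedy forward search walks the ranking (at most `max_n` = 50 candidates)
and keeps a feature only when it strictly improves an inner 3-fold AUC on
the training fold — the inner criterion is this package's choice, since the
reference greedy search never defines one — and an unpenalized logistic
regression (optional L2 via `l2_C`) is scored on the held-out fold by AUC
and accuracy (0.5 threshold). Features appearing in more than 3 of the 50
fold-level sets (≥ 4) form the consolidated signature, reported with k/50
frequencies.

Gene statistics and the walk are computed once on the full cohort — only
ranking and selection are fold-wise. This mirrors the reference protocol and
leaks some label information into the features; the reported AUC should be
read accordingly, and comparisons between methods evaluated under the same
protocol remain fair.

Baselines implemented under the identical evaluation: per-pathway mean or
median of significant member z-values (no walk weights, no effect
directions); concatenation of two independently walked single-layer pathway
profiles (`drw_concat`, no cross-layer edges); and the raw concatenated
gene-level z-profiles (`gene_profile`). The Simpson coefficient
|A∩B|/min(|A|,|B|) compares the differential-gene content of pathway lists
selected by different rankers.

## Synthetic cohorts

The generator emulates the statistical shape of a paired bulk tumor cohort,
not its biology. Pathways are blocks of consecutive genes on a circular gene
list (block stride n_genes/n_pathways, sizes 15–25 by default, so
neighbouring pathways overlap as related pathways do); directed edges are
drawn within pathways at density 0.15 plus a sparse Poisson number of
long-range edges. Expression counts are negative-binomial via gamma-Poisson
with log-normal baseline means (ln-mean ln 100, ln-sd 1) and dispersion 0.3
— the biological coefficient of variation typical of bulk human tumor
cohorts. Methylation is continuous and unbounded (z-scoring downstream makes
the beta-vs-Gaussian distinction immaterial); a fraction `anti_frac` = 0.3
of genes get methylation built from their own expression with loading −0.8
plus independent noise, emulating repressive promoter methylation. Labels
are balanced Bernoulli. Planted pathways multiply the NB mean of their
genes by 2^lfc and shift their methylation by `meth_shift` in the poor
group. Missing methylation values are injected i.i.d.

What passing tests on these cohorts shows: the pipeline recovers planted
differential pathways and its components behave as specified under NB
counts, anti-correlated layers and block pathway structure. What it does not
show: robustness to batch effects, censoring structure, probe-level
artifacts, non-block pathway topologies, or confounded labels — none of
which the generator emulates.

At the standard recovery setting (50 pathways, 5 planted, lfc 1.5,
methylation shift 1.0, n = 300) the planted effects are strong enough that
both the integrated profile and the mean-of-members baseline classify
perfectly (AUC 1.0): the evaluation saturates, so classification comparisons
at this setting can only show the integrated profile is not worse. Ranking
comparisons (which pathways reach the top) remain discriminative.

## Numerical choices and degenerate inputs

* Zero-variance genes: z-scoring raises with the gene named; Welch t on
  identical groups returns t = 0, p = 1 (no evidence) with a warning; zero
  variance with different means returns p = 0 and a large capped t.
* All-zero count genes are excluded from the NB test with a warning.
* A layer whose evidence is constant gets uniform initial weights.
* Transition rows sum to 1 (tolerance 1e-12); W₀ and W∞ are L1-normalized
  to 1e-10; walk/oracle agreement is required to 1e-8 in L1 over random
  graphs up to 100 nodes.
* Problem sizes in the test suite and acceptance script (cohorts of 60–300
  samples, 160–1000 genes, graphs ≤ 100 nodes for oracle comparisons, 1000
  null genes for calibration) were chosen so each check exercises the
  asymptotic behaviour it targets while the whole suite stays quick to run.

## Known limitations

* The NB Wald surrogate has no dispersion shrinkage, independent filtering
  or outlier handling; for real cohorts, inject DESeq2 results through
  `load_external_stats` when exactness matters.
* Full-cohort weighting leaks label information into the features (see
  above); fold-internal re-walking is not implemented.
* The reference gene-gene graph is consumed, never reconstructed; published
  edge counts for specific graphs are not reproduced.
* Edges are unweighted (uniform out-degree transition probabilities); the
  walk is global, not per-sample.
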