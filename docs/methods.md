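# Methods

`sbsl` predicts whether a pair of genes is synthetically lethal (SL) in a
given cancer type from molecular features alone, and—just as importantly—
evaluates such predictors in ways that do not reward memorizing the structure
of the SL label graph. This note documents the models, the statistics, the
synthetic data the package ships with, and the numerical and design choices
a maintainer would want to know about.

## The prediction problem

An SL pair is one where simultaneous loss of function of both genes kills a
cell while loss of either alone does not. Labels come as unordered gene
pairs with a binary SL/non-SL call, a cancer type and a source tag. The
package treats prediction as binary classification of pairs described by 27
real-valued molecular features; a pair is always canonicalized to
lexicographic order, and every feature is exactly invariant to orientation.

## The 27 features

**Gene dependency (10).** For each screen type (CRISPR and RNAi; scores are
oriented so that lower = more essential), five features: the signed
standardized Wilcoxon rank-sum statistic and p-value comparing the
dependency of one gene between cell lines with and without a non-silent
mutation in the partner — computed in both orientations, keeping the
orientation with the smaller p-value; the Pearson correlation of the two
dependency profiles and its two-tailed t-test p-value; and the average of
the two genes' mean dependency scores. The rank-sum test uses exact
enumeration when the pooled sample has ≤ 20 observations and no ties, and a
continuity-corrected normal approximation with midranks otherwise.

**Mutual exclusivity (7).** Three per-event-type hypergeometric tests
(high-level amplification CNV = +2, deletion CNV = −2, non-silent mutation)
plus their Fisher combination; a hypergeometric test on the union
"alteration" event; a DISCOVER-style test; and a margin-preserving
permutation test. The hypergeometric expression is evaluated verbatim as

    p = 1 − Σ_{j=nAB}^{min(nA,nB)} C(nA,j) C(nT−nA, nB−j) / C(nT, nB),

the probability of *strictly fewer* co-altered samples than observed. Note
the tail direction: strong exclusivity yields a small value, but this is a
lower-tail quantity, not a conventional "observed or more extreme" p-value;
it is kept in this published form. All hypergeometric terms are evaluated
through log-gamma representations (via `scipy.stats.hypergeom`), stable to
nT ~ 10⁴.

The DISCOVER-style test fits a rank-1 background p_gs = r_g·c_s to the
alteration matrix by iterative proportional scaling of gene and sample
margins, then evaluates the Poisson-binomial lower tail P(overlap ≤
observed) of the per-sample joint probabilities by dynamic programming. This
keeps the test calibrated when some tumours are globally more altered than
others — exactly the situation that breaks the plain hypergeometric test.

The permutation test (standing in for group-based mutual-exclusivity
search, reduced to the pair level) preserves both gene and sample margins
through random 2×2 checkerboard swaps, with a burn-in of 5·nnz swap
attempts and nnz attempts between samples; p = (1 + #{overlap ≤ observed}) /
(1 + n_perm). Inside `build_feature_table` all pairs share one
seed-deterministic swap-chain ensemble (default 200 samples); the standalone
operation runs an independent chain per call. A matrix admitting no
checkerboard swap yields p = 1 with a warning.

**Survival (1).** A Cox proportional-hazards model
ln h(t) = ln h0 + β1·s(A,B) + β2·sex + β3·age + β4·race, where s(A,B)
indicates that *both* genes are altered in a patient's tumour (non-silent
mutation, CNV ±2, or expression in the outer 5th percentiles across
patients). The feature is the two-tailed Wald p-value of β1 ≠ 0. The model
is fit by Newton–Raphson with step-halving on the Breslow partial
likelihood; covariates are centered; convergence is declared at a relative
log-likelihood change < 1e−9 (50 iterations maximum; |β| > 50 is treated as
divergence). The baseline hazard drops out of the partial likelihood and is
never estimated. Race enters as a single integer-coded covariate so the
model has exactly the four coefficients above. A pair whose alteration
indicator is constant, or any failed fit, yields a missing feature.

**Co-expression (6).** Pearson correlation and two-tailed t-test p-value of
the pair's expression across tumour samples, matched-normal samples (when
available) and healthy-donor tissue. Correlations are computed on log2
normalized expression — TMM-scaled counts-per-million for count channels and
log2(TPM + 1) for healthy tissue — because on raw read counts library size
alone correlates every pair of genes.

**Differential expression (2).** For each orientation, the expression of one
gene is tested between patients with and without a non-silent mutation in
the partner: counts are TMM- and library-size-equalized, a common negative-
binomial dispersion is estimated across genes by method of moments
(var = μ + φμ², median across genes, floored at 1e−4), and the split of the
gene's total count between the two groups is tested against the conditional
NB null (group sums as NB with size n_g/φ; doubled smaller tail, capped at
1; evaluated on an adaptive window of ±15 standard deviations around the
conditional mode). The reported features are the smaller of the two
orientation p-values and the corresponding log2 fold change of equalized
group means with a 0.5 pseudocount. TMM uses the sample whose upper quartile
of scaled counts is closest to the mean as reference, 30%/5% double trimming
on M/A, precision weights, and rescaling to geometric mean 1.

**Pathway co-participation (1).** The same verbatim hypergeometric
expression applied to pathway-membership counts (nA, nB = pathways
containing each gene, nAB = pathways containing both). Co-participation
evidence is a *high* overlap, so strongly co-participating pairs sit near 1;
the expression is kept in its published orientation, and the downstream
classifiers are indifferent to monotone orientation.

**Missing values** are genuinely missing (NaN), never zero; imputation is
the evaluation layer's responsibility and uses train-set medians only.

### Calibration of the p-value features

Under the all-null generator, the features that are single two-sided test
p-values (dependency and expression correlations, the mutation-only and
union-alteration hypergeometric tests on ~200 patients, the survival Wald
p) are uniform to Kolmogorov–Smirnov precision. Three families are *not*
uniform by construction and cannot be: the orientation-minimum features
(`CRISPR_dep_pvalue`, `RNAi_dep_pvalue`, `diff_exp_pvalue`) follow the
distribution of the minimum of two nearly independent uniforms; the
rare-event hypergeometric features (`discoversl_mutex_amp/del` at realistic
±2 CNV rates of a few percent, and their Fisher combination) are heavily
discrete with an atom at 0; and the inclusive lower-tail tests
(`discover_mutex`, `MUTEX`, `pathway_coparticipation`) are valid but
super-uniform by half an atom width. None of this affects their use as
classifier inputs — a monotone, reproducible score is all the models need —
but it matters if the columns are read as literal significance levels.

## Models

Four regularized classifiers, all deterministic given their seed, all
trained on class-balanced, standardized features:

* **Elastic net** logistic regression minimizing
  (1/n)Σ log-loss + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), via scikit-learn's saga solver
  (C = 1/(nλ)); L1 yields exact zeros.
* **L0L2**: cardinality-constrained ridge logistic regression
  (‖β‖₀ ≤ k, ridge γ) solved approximately by iterative hard thresholding
  with a 1/L gradient step, Newton polishing on the active support, and
  local single-swap refinement; the (k, γ) grid is selected by repeated CV.
  The support constraint is never exceeded. This is an approximate
  best-subset solver, documented as such.
* **RRF-style forest**: a random forest (Gini, per-tree bootstrap,
  min_samples_leaf 5) in which a candidate split on a feature not yet used
  anywhere in the forest has its impurity gain multiplied by coefReg ∈
  (0, 1]; trees are grown sequentially so the used-feature set accumulates.
  coefReg = 1 is exactly a plain random forest. Implemented with numba
  kernels; 500 trees for final fits.
* **MUVR-style forest**: repeated (nRep) nOuter-fold outer CV with geometric
  backward feature elimination (keep ⌊varRatio·p⌋ by impurity importance per
  step); the optimal feature count per fold is the smallest count maximizing
  validation AUROC, and the final model is refit on all training data with
  the "mid" count — the rounded geometric mean of the smallest and largest
  per-fold optima. Inner forests are plain random forests (scikit-learn).

**Hyperparameter search** is repeated stratified k-fold CV (default 10
folds × 5 repeats) scored by AUROC on the training set only. Selection uses
the one-standard-error rule: among grid points within one SE of the best
mean AUROC, the most strongly regularized wins (larger λ, then smaller k,
then smaller coefReg/mtry). The SE uses the Nadeau–Bengio variance
correction (folds share training data, so the naive sd/√J understates the
CV mean's variance). On pure-noise data this reliably selects the
high-regularization end of the grid; with real signal it does not override
clear differences. Default grids cover the declared spaces (α, λ ∈ [0, 1];
mtry ∈ {4, 8}; coefReg ∈ [0.5, 1]; support sizes with two ridge strengths);
the full-size published grids (20 γ × 50 support values, nRep 5 / nOuter
10 / varRatio 0.8) are accepted by the API but the bundled benchmarks use
the desk-scale versions below.

## Evaluation protocol

Each experiment comprises n_runs (default 10) independent runs. Per run:
re-draw the uniform downsample balancing the two classes; split 70/30
(test size by round-half-even); impute missing features with train medians,
drop features ≥ 95% constant on train, standardize both sides with train
mean/sd; tune on train only; fit on the full train side; report held-out
AUROC (tie-corrected Mann–Whitney) and AUPRC (interpolation-free step-curve
sum). Means ± sd over runs; failed runs are recorded with their error,
never dropped.

**Gene-holdout splits.** `none` is pair-disjoint only. `single` and
`double` first partition the gene universe into train and test gene sets
(the held-out gene fraction is solved so the retained test side approximates
the requested 30%): train pairs have both genes on the train side; single
test pairs have exactly one gene held out (and their train-side gene must
occur in at least one retained train pair); double test pairs have both
genes held out. Pairs compatible with neither side are dropped and reported
via `retained_fraction`. Infeasible configurations (e.g. double holdout on
a small dense clique) raise rather than degrade.

**Cross-dataset evaluation** trains on one label source and tests on
another, removing shared pairs from the train side only. **Grouped
evaluation** covers leave-one-cancer-out (train on the other groups, test on
the held-out one) and pan-cancer training with `balanced` (equal group ×
class counts by undersampling) or `unbalanced` (native proportions)
mixtures, reporting per-group test metrics.

**Diagnostics.** Permutation feature importance is the mean held-out AUROC
drop over within-column permutations. VIFs come from regressing each
standardized feature on the others (exact collinearity → +inf sentinel).
Label-graph bias diagnostics report gene coverage, the labelled fraction
under both natural denominators (pairs / C(g, 2) and pairs / (g²/2) — both
appear in the literature), per-gene degrees, the greedy minimal gene set
covering a requested fraction of pairs, and the signed adjacency ordered by
complete-linkage hierarchical clustering (Euclidean distance) for plotting.

**The label-graph memorizer** (`sbsl.baselines.LabelGraphBaseline`) is a
deliberately identity-driven reference: it scores a pair by a
similarity-weighted vote over training labels, with gene similarity the
clipped cosine of signed label-adjacency rows. It is the executable
demonstration of what selection bias rewards — excellent under pair-disjoint
splits on biased labels, exactly chance under double holdout — and is not an
SBSL model.

## The synthetic-data generator

The generator emulates the statistical structure the features assume, with
one planted effect per data channel, all driven by one master seed (child
generators per channel by fixed offsets; identical configs are
bit-identical):

* **Cell-line panel**: per-gene mutation rates uniform on
  `mutation_rate_range` (default 0.05–0.35, the range of commonly analyzed
  cancer genes); dependency scores Normal(μ_g, σ²) with per-gene baselines
  (CRISPR σ = 0.5, RNAi σ = 0.8 — RNAi screens are noisier); for each
  positive pair, the dependency of each gene is shifted by −`dep_shift` in
  lines where the partner is mutated.
* **Tumour alterations**: rank-1 background r_g·c_s clipped to [0, 0.95],
  with per-patient factors c_s lognormal (sd 0.25) so that DISCOVER-style
  background estimation is meaningful; exclusivity is planted by thinning
  joint events of positive pairs (each joint event loses one side with
  probability 1 − `excl_factor`), approximately preserving margins. CNV ±2
  events are independent with small rates (3% each) and thinned the same
  way; ±1 states (5%) carry no signal, matching features that only use ±2.
* **Counts**: negative binomial (dispersion 0.15, log-normal per-gene means
  around 100 reads, lognormal library factors); the mean of each positive-
  pair gene is scaled by 2^`expr_logFC` in patients whose partner is
  mutated.
* **Healthy/normal expression**: a latent Gaussian factor per positive pair
  gives pairwise correlation `coexpr_rho` (diluted as ρ/√(d_A d_B) for genes
  in several positive pairs); healthy tissue is log-normal TPM, matched
  normal is NB counts on the same latent structure.
* **Survival**: exponential times from
  h0·exp(β1·s + β2·sex + β3·age + β4·race) with h0 = 1/1000 days, age ~
  U(30, 85), sex/race categorical with fixed frequencies and null
  coefficients by default — present because the Cox model controls for
  them, not informative. Only one *designated* positive pair (the first)
  drives the planted hazard; a single global survival outcome cannot carry
  an independent effect per pair. Its genes get the top alteration rate so
  β1 is estimable at the bundled sample sizes. Censoring is independent
  exponential with rate chosen to censor `censor_frac` of baseline patients.
* **Pathways**: 50 random gene sets of 10–40 genes; each positive pair is
  co-assigned to a random common pathway with probability
  `pathway_coassign`.
* **Label bias**: `uniform` sampling without replacement; `hub` concentrates
  a configurable fraction of pairs on k hub genes; `block` partitions genes
  into blocks and labels pairs by their block pair (flipped with
  `block_noise`), producing the near-identical label rows characteristic of
  selection-biased gold standards.

What the generator does **not** emulate: real marginal distributions of
dependency scores or expression, gene-length and GC effects, co-occurring
(rather than exclusive) driver structure, correlated mutation processes,
informative censoring, or real gene symbols. Passing tests therefore show
that the pipeline recovers the *kinds* of signal the features target at
realistic sizes and noise levels — not that real cohorts contain such
signal.

Negative pairs are generated as pure nulls; experimentally derived
non-hits in real screens are plausibly enriched for weak interactions, which
the generator does not model.

## Problem sizes of the bundled benchmarks

The test suite and the reproduction script run the full pipeline at desk
scale: null calibration uses five seeds of 500 pairs × 100 cell lines × 200
patients; the planted-signal benchmark uses 500 + 500 pairs (300 genes) with
10 evaluation runs; the bias experiment uses 50 genes with 600 labelled
pairs (~49% coverage — the dense, near-identical-row regime that selection
bias produces in the most biased real cohorts). Inside cross-validation
loops the forests use reduced tree counts (50-tree RRF, single-repetition
MUVR with 30-tree inner forests); final fits use the full settings. These
sizes are the package's own benchmark design; all entry points accept larger
values.

## Known limitations

* The L0L2 solver is approximate; for p ≫ 100 features or large supports an
  exact best-subset solver would be preferable.
* The permutation-exclusivity feature shares one null ensemble across pairs
  within a table, introducing weak dependence between pair p-values
  (irrelevant for classification, visible in extreme-tail joint statements).
* The common-dispersion NB test is calibrated under the generator but lacks
  empirical-Bayes tagwise shrinkage; very heterogeneous real count data
  would deserve a dedicated DE package.
* The Cox feature uses integer-coded race, which imposes an ordering a
  dummy expansion would not; with null race effects this is harmless, with
  real data it is a modelling choice to revisit.
* Survival signal attaches to a single designated pair, so `logrank_pval`
  contributes no class separation in the planted benchmark; it is exercised
  through the effect-size recovery check instead.
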