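# Methods

This note documents the models, defaults and numerical choices behind
`brafsig`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the procedure was genuinely open.

## Data model and conventions

Expression matrices are genes × samples with a declared scale
(`log2`, `vst`, `zscore_gene`, `zscore_sample`, `raw`); missing values
are not permitted (drug IC50 tables are the one exception, handled
complete-case per drug).  Gene identifiers are case-sensitive symbols
with no alias mapping.  Z-scoring uses the sample standard deviation
(n−1 denominator) throughout; this is asserted by tests
(per-unit |mean| < 1e−10, |SD − 1| < 1e−10).  All writers emit
deterministic column order; GMT and expression round-trips preserve
values to 1e−12.

## Signature derivation

**Immune pruning.**  Founder sets are pruned against an editable
blocklist of immune-lineage markers (pan-leukocyte, T/B/NK, myeloid;
`brafsig/data/immune_blocklist.txt`).  The default list is deliberately
coarse — its job is to remove obvious tumor-microenvironment signal, not
to be a definitive immune catalogue.

**Expression/variance filter.**  Per gene we compute mean log2
expression and the log coefficient of variation.  The CV is computed on
the linear scale (2^x) and then natural-logged; a config flag switches
to log2-scale CV.  A tricube-weighted local linear regression
(span 0.5, two robustness iterations; `statsmodels` lowess) of log-CV on
mean expression is fit over **all** genes, and signature genes survive
when their residual is positive and mean expression exceeds 6 (log2
units).  Constant genes (log-CV = −∞) are excluded outright.  The fit is
cross-checked in the tests against an independently written tricube
local-linear implementation rather than bit-matched, because lowess
variants legitimately differ in interpolation details; the two
implementations agree everywhere except genes within ±0.15 of the fitted
trend.

**Stratification.**  Samples are clustered on the signature submatrix
with Ward linkage on Euclidean distances (the Ward.D2 convention:
squared distances enter the Lance–Williams update), cut at k = 3, and
clusters are relabelled low / unclassified / high by ascending mean
signature expression; ties break by the smaller original cluster index.

**Screening.**  Pearson chi-square without continuity correction
(configurable) on the 2×2 mutant/WT × high/low table, unclassified
samples excluded; founder sets rank by ascending p with an alphabetical
tie-break.

**Moderated differential expression.**  Per-gene two-group comparison
with empirical-Bayes variance moderation: pooled variance
s²_g (d_g df), prior (d₀, s₀²) estimated by matching the mean and excess
variance of log s²_g to the digamma/trigamma moments of the scaled-F
model, moderated t referred to d₀ + d_g df, BH-adjusted.  Setting the
prior df to 0 reproduces the ordinary pooled-variance t exactly (tested
to 1e−8); an infinite prior shrinks fully to s₀².  Two threshold presets
exist because the source procedure is described with two conventions:
`methods` (fold change > 2, i.e. log2FC > 1, FDR < 0.01 — the default)
and `strict` (log2FC > 2, p < 1e−10).  Only upregulated genes are
merged.

## Panel selection

**Tumor dominance.**  Per candidate gene, a one-sided Wilcoxon rank-sum
of tumor vs pooled non-tumor cells (alternative: tumor greater).  For
small tie-free samples the exact tail is used (the 5-vs-5
complete-separation case equals 1/252), otherwise the normal
approximation with tie correction.  Ordering: p ascending, then
descending mean difference, then gene id; absent candidates rank last.

**Robust rank aggregation.**  Ranks are normalized by the gene-universe
size; genes absent from a list get normalized rank 1 (maximally
pessimistic).  With order statistics r₍₁₎ ≤ … ≤ r₍ₖ₎, β_j is the
binomial upper tail Σ_{i≥j} C(k,i) r₍ⱼ₎^i (1−r₍ⱼ₎)^{k−i}; the score is
min_j β_j, Bonferroni-multiplied by k and capped at 1.  The tests verify
this against the equivalent beta-distribution closed form exhaustively
for k ≤ 3, n ≤ 6 and against Monte-Carlo order-statistic estimates for
k = 4.

**Selection rule.**  Two rules are exposed for reducing the aggregate
to the stepwise input: a corrected-score threshold (< 0.05) and a
presence filter (every gene appearing in ≥ 1 list, aggregate order).
The end-to-end chain uses the presence filter: over a ~25-gene candidate
universe the normalized ranks cannot reach extreme values, so the score
threshold empties the panel at desk scale even for genes ranked near the
top of all four lists.

**Stepwise growth.**  For each prefix of the aggregate order the samples
are re-stratified (k = 3) on the prefix and the classification accuracy
recorded; the reported panel is the smallest prefix attaining the
maximal accuracy (first-maximum rule).  The unclassified-cluster policy
defaults to *penalized* — an unclassified mutant counts as FN, an
unclassified WT as FP — with `unclassified_dropped` available.  On
two-population synthetic data the forced third cluster is a noise
partition of one population (Ward's merge cost grows with cluster size,
so the larger WT population splits), which caps penalized accuracy well
below what graded real cohorts show; the dropped policy saturates at
accuracy 1 almost immediately.  This interaction is a structural
property of clustering two-population data into three groups, not an
estimation error, and it means the selected panel size on such data
reflects where cluster noise happens to be most favorable.  See the
repository test suite for the quantitative consequences.

## Scoring and subtyping

**ssGSEA.**  Within each sample genes are ranked ascending with
expression (ties share average rank) and walked in descending order; the
score is Σ_i (ECDF_in(i) − ECDF_out(i)) with the in-set ECDF weighted by
rank^α (α = 0.25 default; the 4-gene α = 1 worked example evaluates to
exactly 2.0).  Scores depend only on within-sample ranks and are
invariant to any strictly increasing per-sample transform (property
tested under random monotone maps).  The gene set may not cover the
whole matrix (the out-of-set ECDF would be undefined).  Optional
normalization divides by the score range across samples.

**Activity index.**  Both definitions in circulation are first-class:
the ssGSEA score (default) and mean signature expression.  On data with
a planted signal they are strongly rank-concordant (Spearman > 0.9 in
tests); only the mean is on the expression scale.

**BAGs.**  Ward clustering cut at k = 4 (configurable), labels
BAG-0 … BAG-3 ascending by mean signature expression; the mean ordering
is an invariant asserted on arbitrary inputs.

**Discrimination.**  ROC points from all thresholds plus (0,0) and
(1,1); the upper convex hull is computed by a monotone chain and its
exact polygon area is the hull AUROC (≥ the trapezoidal AUROC by
construction).  AUPRC uses step-wise interpolation (no linear PR
segments), the conservative convention under class imbalance.

## Transfer classifier

Per-gene z-scoring makes features comparable across cohorts; external
matrices must be flagged `zscore_gene` or prediction aborts.  (The
pan-cancer integration instead z-scores per sample, as its contract
states.)  The stratified 80/20 split is per-class proportional and
seed-deterministic.  The redundancy filter greedily removes, from the
currently worst pair, the member with the larger mean absolute
correlation (lexicographic tie-break) until no pair exceeds |r| = 0.8 —
the survivors provably contain no violating pair.  Random-forest
importance (mean impurity decrease, 500 trees, seeded) ranks features;
stepwise RBF-SVM selection scans γ ∈ {2⁻⁷…2³}, C ∈ {2⁻³…2⁷}
(log-spaced, documented and configurable — no canonical grid exists)
under stratified 5-fold CV with inverse-frequency class weights, and the
smallest prefix attaining maximal CV accuracy is refit on the full
training set.  End-to-end determinism given (data, config, seed) is
tested.

## Downstream analyses

**Drugs.**  Per drug, OLS of log2 IC50 on the high-activity indicator
adjusted for mutation status (complete-case, ≥ 3 lines per group, rank
checks for collinearity); the group coefficient is Δlog2 IC50 (negative
= sensitive in the high-activity group), tested two-sided, BH-adjusted;
hits need FDR < 0.05 and |Δ| > 1.  When a drug appears in two screens
the occurrence with the smaller raw p is kept.  Category enrichment is
the hypergeometric upper tail P(X ≥ k) per target category, BH across
categories, sensitive and resistant hit sets tested separately.

**Survival.**  The k-group log-rank statistic is implemented directly
(observed − expected with the hypergeometric variance, so tied event
times are handled) and cross-checked against an established
implementation; Cox models are fit by partial-likelihood maximization
through an established routine behind the `cox_fit` contract (HR, Wald
CI and p per term; < 10 events per parameter warns; non-convergence
raises naming the terms; empty factor levels are dropped with a
warning).  Restricted cubic splines use the truncated-power natural
basis with knots at the 10/50/90 percentiles for three knots (the common
convention; only the knot count is prescribed), giving k−1 design
columns that are linear beyond the boundary knots.  Activity tertiles
split at the 1/3 and 2/3 quantiles with boundary ties to the lower
group; survival tertiles are computed per cohort, not pooled.

**Pan-cancer.**  Cohort summaries (mean activity index, pathway
mutation ratio) are correlated by Spearman's rank correlation; cohorts
are split into active/quiet at the deepest density minimum between the
two largest modes of a Gaussian KDE (Silverman bandwidth), with a
median-split fallback (warned) for unimodal inputs; the higher-mean
group is `active`.  The pathway-membership list (RTKs, RAS, RAF,
MAP2K1/2, MAPK1/3) ships as an editable default because only the
exclusion list, not the full cascade roster, is prescribed.

## Synthetic data

One integer seed drives a named child stream per artifact, so adding a
generator never perturbs the others; all generators are pure functions
of (config, seed).  Defaults are the study conditions used by the tests
and the acceptance script:

- **Cell-line compendium** — 2000 genes × 200 lines; gene means
  Uniform(4, 12) on log2 (so the mean > 6 filter removes a predictable
  fraction); mutant fraction 0.25; a 25-gene signature planted at
  +2.0 log2 in mutants over Normal(μ_g, 0.5) noise; 15% of lines carry
  non-BRAF pathway mutations for exclusion tests.
- **Founder sets** — 8 sets, each a disjoint slice of the planted
  signature plus 10 decoy background genes and 5 low-expression genes;
  components are drawn without replacement so pairwise overlap is
  confined to the (disjoint) planted cores.
- **Single cell** — 100 cells per type (tumor, fibroblast, T, B,
  myeloid); 80% of candidates shifted +2.0 in tumor cells; independent
  dataset streams emulate the four ranked lists.
- **Survival** — exponential event times (chosen over Weibull for
  closed-form checks), hazard h₀·HR^group, independent exponential
  censoring tuned to the target censoring fraction; age/sex/stage
  covariates.
- **Drugs** — 60 drugs across six target categories; the planted
  sensitive category shifts IC50 by −2 log2 in high-activity lines;
  others null.
- **BAG cohorts** — four balanced groups at adjacent-mean separation
  2.0 log2 on 25 signature genes with within-group SD 1.5, chosen so
  pairwise signature-gene correlations (expected |r| ≈ 0.69) sit below
  the 0.8 redundancy cutoff, matching the reference observation that no
  signature gene was dropped as redundant.

What the generators deliberately do **not** emulate: single-cell count
distributions (dropout, library size), batch effects, graded/continuous
pathway activity in the compendium (mutant vs WT is binary), or
correlated gene-gene structure beyond the planted group signal.
Consequently, passing tests demonstrate that each stage recovers the
structure it is designed to detect at the stated effect sizes — they do
not certify performance on real cohorts, where activity is graded, the
middle cluster is genuinely intermediate, and signature genes co-vary.

## Problem sizes

The default test suite and the acceptance run use the study-condition
bundle (200 × 2000 compendium; n = 400 transfer cohorts; 500 log-rank
replicates; 2000-gene null DE; 24 pan-cancer cohorts), which completes
in about a minute on one CPU; module tests use a 60 × 300 bundle.
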