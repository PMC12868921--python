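# brafsig

Transcriptional BRAF pathway-activity meta-signature pipeline.

`BRAF` mutation status alone is a poor predictor of outcome and therapy
response: the MAPK cascade can be activated by upstream events (RTK/RAS
mutations, feedback loss, epigenetic changes) in mutation-negative
tumors, and mutant tumors can carry quiescent signaling.  `brafsig`
implements the alternative: measure *pathway activity* from expression.
It derives a compact activity signature from a collection of founder
gene sets and a mutation-labelled expression compendium, scores samples
with it, groups them into ordered **BRAF activity groups (BAGs)**,
transfers the grouping to external cohorts with a classifier, and runs
the downstream drug-sensitivity, survival and pan-cancer analyses.
Every stage is exercisable on synthetic data with planted ground truth,
so the full pipeline is testable without any external downloads.

## The method

**Signature derivation.** Founder gene sets are pruned of immune-lineage
genes, then filtered against the compendium: a tricube local-linear
regression of log coefficient of variation on mean log2 expression is
fit over all genes, and signature genes are kept when their residual is
positive and mean log2 expression exceeds 6.  For each filtered set,
samples are stratified by Ward (Ward.D2) hierarchical clustering on the
signature submatrix into *low / unclassified / high* activity groups
(ordered by mean signature expression), and the set is scored by the
Pearson chi-square of mutant/WT status against high/low membership.
The most discriminative sets are refined by empirical-Bayes moderated
differential expression (limma-style variance shrinkage: per-gene
pooled variance s&sup2;<sub>g</sub> shrunk toward a moment-matched
scaled-F prior), and upregulated genes passing fold-change/FDR
thresholds are merged into the meta-signature.

**Panel selection.** Candidate genes are ranked per single-cell dataset
by one-sided Wilcoxon tumor-vs-rest dominance, aggregated by robust
rank aggregation — for normalized ranks r<sub>(1)</sub> ≤ … ≤
r<sub>(k)</sub> over k lists, the score is
min<sub>j</sub> P(U<sub>(j)</sub> ≤ r<sub>(j)</sub>) under the uniform
null, Bonferroni-corrected by k — and grown one gene at a time; each
prefix is scored by Accuracy = (TP+TN)/(TP+TN+FP+FN) of placing mutant
samples in the high-activity cluster, with the Youden index
(sensitivity + specificity − 1) reported alongside.

**Scoring and subtyping.** The per-sample activity index is either the
single-sample GSEA enrichment score of the signature (rank-weighted
running difference between in-set and out-of-set ECDFs, exponent
α = 0.25) or mean signature expression.  Samples are clustered into k=4
BAGs (BAG-0 … BAG-3, ascending activity).  Mutation discrimination is
summarized by the AUROC of the convex hull of the ROC curve and, for
imbalanced cohorts, the AUPRC.

**Transfer and downstream.** An RBF-kernel SVM (stratified 80/20 split,
|r| > 0.8 redundancy filter, random-forest importance ranking, stepwise
feature selection under 5-fold CV) reproduces BAG labels in z-scored
external cohorts.  Drug response is modelled per drug as
log2 IC50 ~ activity + mutation (OLS), with BH-FDR hit calling and
hypergeometric target-category enrichment; survival uses the k-group
log-rank test and Cox proportional-hazards models with restricted-cubic-
spline age and activity × mutation interactions; pan-cancer structure is
the Spearman correlation of cohort mean activity with pathway mutation
burden plus a kernel-density split into active/quiet cohorts.

## Worked example

```python
from brafsig import SimulationConfig, braf_index, roc_convex_hull_auc
from brafsig.workflow import derive_panel_chain

config = SimulationConfig(seed=11, n_genes=300, n_samples=60)
result = derive_panel_chain(config)
print(f"merged meta-signature: {len(result.merged.genes)} genes "
      f"({100 * result.merged_recovery:.0f}% of planted signal recovered)")
print(f"selected panel: {result.trace.optimal_size} genes, "
      f"accuracy {result.trace.optimal_accuracy:.3f}")

index = braf_index(result.cohort.expression, result.merged, method="ssgsea")
status = result.cohort.mutations.status_for("BRAF", index.values.index.tolist())
roc = roc_convex_hull_auc(index, (status == "mutant").astype(int))
print(f"mutant discrimination: hull AUROC {roc.auroc_hull:.3f}, AUPRC {roc.auprc:.3f}")
```

prints

```
merged meta-signature: 25 genes (100% of planted signal recovered)
selected panel: 6 genes, accuracy 0.902
mutant discrimination: hull AUROC 1.000, AUPRC 1.000
```

The simulated compendium plants a 25-gene upregulation in mutant cell
lines; the derivation chain recovers all of it in the merged signature,
the stepwise rule settles on a 6-gene panel classifying 90% of lines
correctly under the conservative policy that counts the middle cluster
as an error, and the resulting activity index separates mutant from WT
lines perfectly on this small bundle.

A `brafsig` console script exposes each stage
(`simulate`, `derive`, `panel`, `score`, `classify`, `drugscan`,
`survival`, `pancancer`, `defaults`, `run`); `brafsig run --config
config.yaml` executes the pipeline end-to-end and writes a manifest with
output hashes.

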