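"""Rank aggregation and stepwise gene-panel selection.

Candidate genes are ranked per single-cell dataset by tumor-dominant
expression, the ranked lists are combined by robust rank aggregation
(order-statistic probabilities under a uniform null), and the panel is
grown one gene at a time, each prefix scored by its ability to place
mutant samples in the high-activity cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ClassificationCounts,
    ExpressionMatrix,
    GeneSet,
    GroupAssignment,
    MutationTable,
)
from .derive import stratify_by_signature
from .simulate import ScrnaTable


@dataclass
class RankedGeneList:
    """Genes ordered by a per-dataset score (ascending; id tie-break)."""

    source: str
    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"ranked list {self.source!r} contains duplicate genes")


def tumor_dominance_ranking(
    scrna: ScrnaTable,
    candidate_genes: Sequence[str],
    tumor_label: str = "tumor",
) -> RankedGeneList:
    """Rank candidates by one-sided tumor-vs-rest rank-sum significance.

    Per gene, tumor cells are compared against all pooled non-tumor cells
    with a one-sided Wilcoxon rank-sum test (alternative: tumor greater;
    exact tail for small tie-free samples, otherwise normal approximation
    with tie correction).  Order: p ascending, then descending tumor -
    non-tumor mean difference, then gene id.  Candidates absent from the
    table rank last with score 1.
    """
    labels = scrna.cell_labels
    tumor_cells = labels.index[labels == tumor_label]
    other_cells = labels.index[labels != tumor_label]
    if len(tumor_cells) == 0:
        raise ValueError(f"no cells labelled {tumor_label!r}")
    if len(other_cells) == 0:
        raise ValueError("no non-tumor cells to compare against")

    rows = []
    for gene in candidate_genes:
        if gene not in scrna.values.index:
            rows.append((gene, 1.0, -np.inf))
            continue
        x = scrna.values.loc[gene, tumor_cells].to_numpy()
        y = scrna.values.loc[gene, other_cells].to_numpy()
        res = stats.mannwhitneyu(x, y, alternative="greater", method="auto")
        rows.append((gene, float(res.pvalue), float(x.mean() - y.mean())))
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return RankedGeneList(
        source=getattr(scrna, "source", "scrna"),
        genes=tuple(r[0] for r in rows),
        scores=tuple(r[1] for r in rows),
    )


# ---------------------------------------------------------------------------
# Robust rank aggregation
# ---------------------------------------------------------------------------


@dataclass
class RRAResult:
    """Aggregate order with per-gene corrected rho scores."""

    scores: pd.Series  # gene -> corrected rho, ascending = better

    @property
    def order(self) -> list[str]:
        return list(self.scores.index)


def _rho(normalized_ranks: np.ndarray, k: int) -> float:
    """min over order statistics j of P(U_(j) <= r_(j)) for k iid U(0,1),
    evaluated through the binomial tail."""
    r = np.sort(normalized_ranks)
    betas = [float(stats.binom.sf(j - 1, k, r[j - 1])) for j in range(1, k + 1)]
    return min(betas)


def rra_aggregate(
    lists: Sequence[RankedGeneList], gene_universe_size: int | None = None
) -> RRAResult:
    """Robust rank aggregation of ranked gene lists.

    Each gene's rank in each list is normalized by the gene-universe size
    (genes absent from a list get normalized rank 1, maximally
    pessimistic).  The rho score is the minimum over order statistics j of
    the probability that the j-th smallest of k iid Uniform(0,1) variables
    falls at or below the observed normalized rank, and is Bonferroni
    corrected by the number of lists (capped at 1).  Genes are ordered by
    ascending corrected score with lexicographic id tie-break.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    for lst in lists:
        if len(lst.genes) == 0:
            raise ValueError(f"ranked list {lst.source!r} is empty")
    max_len = max(len(lst.genes) for lst in lists)
    if gene_universe_size is None:
        gene_universe_size = max_len
    if gene_universe_size < max_len:
        raise ValueError(
            f"gene_universe_size {gene_universe_size} < longest list {max_len}"
        )

    universe = sorted({g for lst in lists for g in lst.genes})
    k = len(lists)
    rank_maps = [
        {g: (i + 1) / gene_universe_size for i, g in enumerate(lst.genes)}
        for lst in lists
    ]
    scores = {}
    for gene in universe:
        r = np.array([rm.get(gene, 1.0) for rm in rank_maps])
        scores[gene] = min(_rho(r, k) * k, 1.0)
    series = pd.Series(scores, name="rra_score")
    series = series.iloc[np.lexsort((series.index, series.to_numpy()))]
    return RRAResult(series)


def select_aggregated_genes(
    rra_result: RRAResult,
    score_max: float | None = 0.05,
    top_n: int | None = None,
    name: str = "aggregated",
) -> GeneSet:
    """Genes passing the corrected-score threshold (or the best ``top_n``),
    in aggregate order."""
    if len(rra_result.scores) == 0:
        raise ValueError("empty RRA result")
    if top_n is not None:
        genes = rra_result.order[:top_n]
    else:
        genes = [g for g, s in rra_result.scores.items() if s < score_max]
    if not genes:
        raise ValueError("no genes pass the aggregation threshold")
    return GeneSet(name, tuple(genes), provenance="RRA-aggregated")


# ---------------------------------------------------------------------------
# Classification bookkeeping
# ---------------------------------------------------------------------------

POLICIES = ("unclassified_penalized", "unclassified_dropped")


def classification_counts(
    assignment: GroupAssignment,
    mutations: MutationTable,
    target_gene: str = "BRAF",
    policy: str = "unclassified_penalized",
) -> ClassificationCounts:
    """Confusion counts of mutation status against activity grouping.

    TP = mutants in high, TN = WT in low.  Under the default policy an
    unclassified mutant counts as FN and an unclassified WT as FP (the
    middle cluster is a classification failure); ``unclassified_dropped``
    removes those samples from the denominator instead.  Samples with
    unknown mutation status are dropped with a warning.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    status = mutations.status_for(target_gene, assignment.sample_ids)
    unknown = status[status == "unknown"].index
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} samples with unknown {target_gene} status dropped"
        )
    keep = status.index[status != "unknown"]
    labels = assignment.labels.loc[keep]
    status = status.loc[keep]
    if policy == "unclassified_dropped":
        mask = labels != "unclassified"
        labels, status = labels[mask], status[mask]
    mut = status == "mutant"
    tp = int((mut & (labels == "high")).sum())
    tn = int((~mut & (labels == "low")).sum())
    fn = int((mut & (labels != "high")).sum())
    fp = int((~mut & (labels != "low")).sum())
    return ClassificationCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(counts: ClassificationCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and Youden index from counts.

    accuracy = (TP+TN) / (TP+TN+FP+FN); sensitivity = TP / (TP+FN);
    specificity = TN / (TN+FP); youden = sensitivity + specificity - 1.
    A metric whose denominator is zero is returned as None (undefined)
    rather than NaN; all-zero counts are an error.
    """
    if counts.total == 0:
        raise ValueError("all counts are zero; metrics undefined")
    accuracy = (counts.tp + counts.tn) / counts.total
    sensitivity = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    specificity = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    youden = (
        sensitivity + specificity - 1.0
        if sensitivity is not None and specificity is not None
        else None
    )
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "youden": youden,
    }


# ---------------------------------------------------------------------------
# Stepwise panel growth
# ---------------------------------------------------------------------------


@dataclass
class PanelSelectionTrace:
    """Per-size accuracy trace of the growing panel plus the selected
    optimum (smallest size attaining maximal accuracy)."""

    steps: pd.DataFrame  # columns: size, gene_added, tp, tn, fp, fn, accuracy
    optimal_size: int
    panel: GeneSet

    def accuracy_at(self, size: int) -> float:
        return float(self.steps.set_index("size").loc[size, "accuracy"])

    @property
    def optimal_accuracy(self) -> float:
        return self.accuracy_at(self.optimal_size)


def stepwise_panel(
    ranked_genes: Sequence[str],
    matrix: ExpressionMatrix,
    mutations: MutationTable,
    max_size: int | None = None,
    target_gene: str = "BRAF",
    policy: str = "unclassified_penalized",
    panel_name: str = "panel",
) -> PanelSelectionTrace:
    """Grow the panel one ranked gene at a time and keep the first maximum.

    For each prefix of the ranked list, samples are stratified into three
    activity groups on that prefix, confusion counts computed against
    mutation status, and the accuracy recorded.  The reported panel is the
    smallest prefix attaining the maximal accuracy.
    """
    ranked = [g for g in ranked_genes if g in matrix.values.index]
    missing = set(ranked_genes) - set(ranked)
    if missing:
        raise ValueError(f"ranked genes absent from matrix: {sorted(missing)[:5]}")
    if max_size is None:
        max_size = len(ranked)
    if max_size > len(ranked):
        raise ValueError(f"max_size {max_size} exceeds ranked list length {len(ranked)}")

    rows = []
    for size in range(1, max_size + 1):
        prefix = ranked[:size]
        assignment = stratify_by_signature(matrix, prefix, k=3)
        counts = classification_counts(
            assignment, mutations, target_gene=target_gene, policy=policy
        )
        metrics = classification_metrics(counts)
        rows.append(
            (
                size,
                prefix[-1],
                counts.tp,
                counts.tn,
                counts.fp,
                counts.fn,
                metrics["accuracy"],
            )
        )
    steps = pd.DataFrame(
        rows, columns=["size", "gene_added", "tp", "tn", "fp", "fn", "accuracy"]
    )
    best = int(steps.loc[steps["accuracy"].idxmax(), "size"])  # idxmax -> first max
    panel = GeneSet(panel_name, tuple(ranked[:best]), provenance="stepwise-selected")
    return PanelSelectionTrace(steps=steps, optimal_size=best, panel=panel)
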