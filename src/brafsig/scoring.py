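"""Per-sample activity scoring and activity-group (BAG) assignment.

The activity index of a sample is either its single-sample GSEA
enrichment score for the signature (rank-weighted cumulative difference
between in-set and out-of-set empirical distributions) or the plain mean
signature expression.  Samples are grouped into BAGs by Ward clustering
on the signature submatrix, ordered by increasing mean signature
expression, and the index's ability to discriminate mutant samples is
summarized by the convex-hull AUROC and the AUPRC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, roc_curve

from .core import ExpressionMatrix, GeneSet, GroupAssignment, MutationTable, bag_vocabulary
from .derive import _order_clusters, _ward_groups


@dataclass
class IndexVector:
    values: pd.Series  # sample -> index
    method: str  # "ssgsea" | "mean_expression"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("index contains non-finite values")


def ssgsea(
    matrix: ExpressionMatrix,
    geneset: GeneSet | Sequence[str],
    alpha: float = 0.25,
    normalize: bool = False,
) -> IndexVector:
    """Single-sample GSEA enrichment score per sample.

    Within each sample, genes are ranked by expression (lowest rank 1,
    highest rank N, ties sharing the average rank) and walked in
    descending-expression order; the score is the running sum of the
    difference between the rank-weighted in-set ECDF

        ECDF_in(i) = sum_{j<=i, j in S} z_j**alpha / sum_{j in S} z_j**alpha

    and the unweighted out-of-set ECDF (step 1/(N-|S|)).  With
    ``normalize`` all scores are divided by (max - min) across samples.
    Scores depend on within-sample ranks only, so they are invariant to
    any strictly increasing per-sample transform of the expression values.
    """
    genes = list(geneset.genes) if isinstance(geneset, GeneSet) else list(geneset)
    present = [g for g in genes if g in matrix.values.index]
    if len(present) < 1:
        raise ValueError("no signature genes present in the matrix")
    n = matrix.n_genes
    n_in = len(present)
    if n_in >= n:
        raise ValueError("gene set covers the whole matrix; out-of-set ECDF undefined")

    in_set = matrix.values.index.isin(present)
    X = matrix.values.to_numpy()
    scores = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        col = X[:, j]
        z = stats.rankdata(col, method="average")  # 1..N ascending with expression
        order = np.argsort(-z, kind="stable")  # descending expression walk
        z_walk = z[order] ** alpha
        in_walk = in_set[order]
        denom_in = z_walk[in_walk].sum()
        ecdf_in = np.cumsum(np.where(in_walk, z_walk, 0.0)) / denom_in
        ecdf_out = np.cumsum(~in_walk) / (n - n_in)
        scores[j] = float(np.sum(ecdf_in - ecdf_out))
    series = pd.Series(scores, index=matrix.sample_ids, name="ssgsea")
    if normalize:
        spread = series.max() - series.min()
        if spread == 0:
            raise ValueError("cannot normalize: all samples share one score")
        series = series / spread
    return IndexVector(series, "ssgsea")


def braf_index(
    matrix: ExpressionMatrix,
    geneset: GeneSet | Sequence[str],
    method: str = "ssgsea",
    alpha: float = 0.25,
) -> IndexVector:
    """Per-sample activity index over the signature.

    ``method='ssgsea'`` gives the enrichment score; ``'mean_expression'``
    the per-sample mean over signature genes.  Both are first-class: the
    two definitions are strongly rank-concordant on data with a real
    planted signal, but only mean expression is on the expression scale.
    """
    if method == "ssgsea":
        return ssgsea(matrix, geneset, alpha=alpha)
    if method == "mean_expression":
        genes = list(geneset.genes) if isinstance(geneset, GeneSet) else list(geneset)
        present = [g for g in genes if g in matrix.values.index]
        if len(present) < 1:
            raise ValueError("no signature genes present in the matrix")
        series = matrix.values.loc[present].mean(axis=0)
        return IndexVector(series.rename("mean_expression"), "mean_expression")
    raise ValueError(f"unknown method {method!r}; expected 'ssgsea' or 'mean_expression'")


def bag_classify(
    matrix: ExpressionMatrix, geneset: GeneSet | Sequence[str], k: int = 4
) -> GroupAssignment:
    """Ward clustering of samples on the signature submatrix into k BAGs.

    Clusters are labelled BAG-0 .. BAG-(k-1) by ascending mean signature
    expression, so mean(BAG-0) <= ... <= mean(BAG-(k-1)) always holds.
    """
    genes = geneset.genes if isinstance(geneset, GeneSet) else tuple(geneset)
    raw, mean_expr = _ward_groups(matrix, genes, k)
    rank_of = _order_clusters(raw, mean_expr)
    vocab = bag_vocabulary(k)
    labels = pd.Series([vocab[rank_of[c]] for c in raw], index=matrix.sample_ids)
    return GroupAssignment(labels, vocab)


# ---------------------------------------------------------------------------
# ROC / PR evaluation
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    points: pd.DataFrame  # columns fpr, tpr (all thresholds + endpoints)
    hull: pd.DataFrame  # upper-hull vertices
    auroc_hull: float
    auroc_trapezoid: float
    auprc: float


def _upper_hull(fpr: np.ndarray, tpr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper convex hull of ROC points (monotone-chain over x-sorted points)."""
    pts = sorted(set(zip(fpr.tolist(), tpr.tolist())))
    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            # keep the chain concave from above: drop the middle point if
            # it lies on or below the segment joining its neighbours
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) >= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    xs, ys = zip(*hull)
    return np.array(xs), np.array(ys)


def roc_convex_hull_auc(index: IndexVector, binary_labels: pd.Series) -> RocResult:
    """ROC curve, its upper convex hull, hull/trapezoid AUROC, and AUPRC.

    ``binary_labels`` is 0/1 per sample (1 = positive class, e.g. mutant),
    aligned with the index by sample id.  The hull always contains (0,0)
    and (1,1), so the hull AUROC dominates the trapezoidal AUROC.  The
    AUPRC uses step-wise interpolation (no linear segments between PR
    points), which is the conservative convention under class imbalance.
    """
    y = binary_labels.loc[index.values.index].to_numpy(dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to compute ROC")
    scores = index.values.to_numpy(dtype=float)
    fpr, tpr, _ = roc_curve(y, scores)
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    hx, hy = _upper_hull(fpr, tpr)
    auroc_hull = float(np.trapezoid(hy, hx))
    auroc_trap = float(_trapezoid_auc(fpr, tpr))
    auprc = float(average_precision_score(y, scores))
    return RocResult(
        points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        hull=pd.DataFrame({"fpr": hx, "tpr": hy}),
        auroc_hull=auroc_hull,
        auroc_trapezoid=auroc_trap,
        auprc=auprc,
    )


def variant_distribution_test(
    mutations: MutationTable,
    bags: GroupAssignment,
    genes_of_interest: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene chi-square of mutant/WT frequency across BAG groups.

    Each gene gives a 2 x k contingency table (mutant/WT rows, BAG
    columns); genes with a degenerate margin (no mutants, or an empty
    BAG row) are skipped with a warning.  Returns a DataFrame with the
    statistic, p-value and a ``flagged`` column (p < alpha).
    """
    rows = []
    samples = bags.sample_ids
    for gene in genes_of_interest:
        status = mutations.status_for(gene, samples)
        known = status[status != "unknown"]
        labels = bags.labels.loc[known.index]
        table = pd.crosstab(known == "mutant", labels)
        table = table.reindex(index=[True, False], columns=list(bags.vocabulary), fill_value=0)
        if (table.sum(axis=1) == 0).any():
            warnings.warn(f"gene {gene!r}: degenerate mutant/WT margin; skipped")
            continue
        keep_cols = table.columns[table.sum(axis=0) > 0]
        table = table[keep_cols]
        if table.shape[1] < 2:
            warnings.warn(f"gene {gene!r}: fewer than two populated groups; skipped")
            continue
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append((gene, float(stat), float(p), p < alpha))
    return pd.DataFrame(rows, columns=["gene", "chi2", "p_value", "flagged"]).set_index(
        "gene"
    )
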