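"""Meta-signature derivation from founder gene sets and a labelled compendium.

The stage mirrors a cell-line screen: founder sets are pruned of immune
genes, filtered for well-expressed high-variance genes (local regression
of log coefficient of variation on mean expression), used to stratify the
compendium into low / unclassified / high activity groups by Ward
clustering, screened by chi-square enrichment of mutants in the high vs
low groups, and the winning signatures are refined by moderated
differential expression whose upregulated genes are merged into the final
meta-signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import ExpressionMatrix, GeneSet, GroupAssignment, MutationTable

THREE_GROUPS = ("low", "unclassified", "high")

# DE threshold presets: "methods" = fold change > 2 with FDR < 0.01;
# "strict" = log2 fold-change > 2 with raw p < 1e-10.
DE_PRESETS = {
    "methods": {"lfc_min": 1.0, "fdr_max": 0.01, "p_max": None},
    "strict": {"lfc_min": 2.0, "fdr_max": None, "p_max": 1e-10},
}


def load_default_blocklist() -> tuple[str, ...]:
    """Immune-lineage gene symbols shipped with the package."""
    text = resources.files("brafsig.data").joinpath("immune_blocklist.txt").read_text()
    genes = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return tuple(genes)


def load_blocklist(path: str | Path | None) -> tuple[str, ...]:
    if path is None:
        return load_default_blocklist()
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return tuple(genes)


def remove_immune_genes(geneset: GeneSet, blocklist: Sequence[str]) -> GeneSet:
    """Drop blocklisted (immune-compartment) genes; order preserved.

    If every gene is blocklisted a warning is emitted and an
    ``EmptyGeneSet`` sentinel is returned (a plain ``GeneSet`` forbids an
    empty gene list).
    """
    block = set(blocklist)
    kept = tuple(g for g in geneset.genes if g not in block)
    if not kept:
        warnings.warn(
            f"gene set {geneset.name!r}: every gene is on the immune blocklist"
        )
        return EmptyGeneSet(geneset.name, geneset.provenance)
    return GeneSet(geneset.name, kept, geneset.provenance)


@dataclass
class EmptyGeneSet:
    """Degenerate result of pruning a set down to nothing."""

    name: str
    provenance: str = ""
    genes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return 0


# ---------------------------------------------------------------------------
# Expression / variance filtering
# ---------------------------------------------------------------------------


def log_cv(matrix: ExpressionMatrix, on_linear_scale: bool = True) -> pd.Series:
    """Per-gene natural log of the coefficient of variation.

    With ``on_linear_scale`` (default) the CV is computed on 2**x values,
    the natural scale for log2 expression input; otherwise directly on the
    stored values.  Genes with zero spread give -inf.
    """
    df = matrix.values
    vals = np.power(2.0, df.to_numpy()) if on_linear_scale else df.to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
        out = np.where(cv > 0, np.log(np.where(cv > 0, cv, 1.0)), -np.inf)
    return pd.Series(out, index=df.index, name="log_cv")


def cv_filter(
    matrix: ExpressionMatrix,
    geneset: GeneSet,
    loess_span: float = 0.5,
    min_mean: float = 6.0,
    cv_on_linear_scale: bool = True,
) -> GeneSet:
    """Retain signature genes above the variance trend and well expressed.

    The log CV is regressed on mean log2 expression over *all* genes with
    a tricube-weighted local linear fit (span ``loess_span``, two
    robustness iterations); signature genes with a positive residual and
    mean expression above ``min_mean`` survive.  Constant genes
    (log CV = -inf) are excluded outright.
    """
    if matrix.n_genes < 10:
        raise ValueError("cv_filter needs at least 10 genes to fit the variance trend")
    present = [g for g in geneset.genes if g in matrix.values.index]
    absent = [g for g in geneset.genes if g not in matrix.values.index]
    if absent:
        warnings.warn(
            f"gene set {geneset.name!r}: {len(absent)} genes absent from the matrix; dropped"
        )

    mean_log2 = matrix.values.mean(axis=1)
    lcv = log_cv(matrix, on_linear_scale=cv_on_linear_scale)
    finite = np.isfinite(lcv.to_numpy())
    fitted = lowess(
        lcv.to_numpy()[finite],
        mean_log2.to_numpy()[finite],
        frac=loess_span,
        it=2,
        xvals=mean_log2.to_numpy(),
    )
    resid = pd.Series(lcv.to_numpy() - fitted, index=matrix.values.index)

    kept = [
        g
        for g in present
        if np.isfinite(lcv[g]) and resid[g] > 0 and mean_log2[g] > min_mean
    ]
    if not kept:
        warnings.warn(f"gene set {geneset.name!r}: no genes survived the CV filter")
        return EmptyGeneSet(geneset.name, geneset.provenance)
    return GeneSet(geneset.name, tuple(kept), geneset.provenance)


# ---------------------------------------------------------------------------
# Ward stratification
# ---------------------------------------------------------------------------


def _ward_groups(matrix: ExpressionMatrix, genes: Sequence[str], k: int) -> tuple[np.ndarray, pd.Series]:
    """Ward-linkage clustering of samples on a gene submatrix.

    Returns raw cluster ids (1..k, dendrogram order) per sample and the
    per-sample mean signature expression used for relabelling.
    """
    present = [g for g in genes if g in matrix.values.index]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    sub = matrix.values.loc[present]
    if k > matrix.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples {matrix.n_samples}")
    X = sub.to_numpy().T  # samples x genes
    Z = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    mean_expr = sub.mean(axis=0)
    return raw, mean_expr


def _order_clusters(raw: np.ndarray, mean_expr: pd.Series) -> dict[int, int]:
    """Map raw cluster ids to ranks by ascending mean signature expression;
    ties broken by the smaller original cluster index."""
    ids = sorted(set(raw.tolist()))
    means = {cid: float(mean_expr.to_numpy()[raw == cid].mean()) for cid in ids}
    ordered = sorted(ids, key=lambda cid: (means[cid], cid))
    return {cid: rank for rank, cid in enumerate(ordered)}


def stratify_by_signature(
    matrix: ExpressionMatrix, geneset: GeneSet | Sequence[str], k: int = 3
) -> GroupAssignment:
    """Ward clustering of samples on the signature submatrix, cut at ``k``.

    For k=3 clusters are relabelled low / unclassified / high by ascending
    mean signature expression; for other k generic ordered labels
    ``level_0..level_{k-1}`` are used.
    """
    genes = geneset.genes if isinstance(geneset, GeneSet) else tuple(geneset)
    raw, mean_expr = _ward_groups(matrix, genes, k)
    rank_of = _order_clusters(raw, mean_expr)
    if k == 3:
        vocab = THREE_GROUPS
    else:
        vocab = tuple(f"level_{i}" for i in range(k))
    labels = pd.Series(
        [vocab[rank_of[c]] for c in raw], index=matrix.sample_ids
    )
    return GroupAssignment(labels, vocab)


# ---------------------------------------------------------------------------
# Chi-square enrichment screen
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentScreenResult:
    signature_name: str
    table: pd.DataFrame  # rows mutant/WT, cols high/low
    statistic: float
    p_value: float


def chi_square_enrichment(
    assignment: GroupAssignment,
    mutations: MutationTable,
    target_gene: str = "BRAF",
    signature_name: str = "",
) -> EnrichmentScreenResult:
    """Pearson chi-square (no continuity correction) of mutant/WT status
    against high/low activity group; unclassified samples are excluded."""
    restricted = assignment.restrict(["high", "low"])
    status = mutations.status_for(target_gene, restricted.sample_ids)
    known = status[status != "unknown"]
    labels = restricted.labels.loc[known.index]
    table = pd.DataFrame(
        {
            "high": [
                int(((known == "mutant") & (labels == "high")).sum()),
                int(((known == "WT") & (labels == "high")).sum()),
            ],
            "low": [
                int(((known == "mutant") & (labels == "low")).sum()),
                int(((known == "WT") & (labels == "low")).sum()),
            ],
        },
        index=["mutant", "WT"],
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate table for {target_gene}: a margin is zero")
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return EnrichmentScreenResult(signature_name, table, float(stat), float(p))


def screen_signatures(
    matrix: ExpressionMatrix,
    mutations: MutationTable,
    founder_sets: Sequence[GeneSet],
    top_m: int = 5,
    target_gene: str = "BRAF",
) -> tuple[list[str], pd.DataFrame]:
    """Stratify + chi-square screen every founder set; rank by ascending
    p-value (alphabetical tie-break) and return the ``top_m`` names with
    the full screen table."""
    rows = []
    for gs in founder_sets:
        if len(gs.genes) < 1:
            continue
        assignment = stratify_by_signature(matrix, gs, k=3)
        res = chi_square_enrichment(
            assignment, mutations, target_gene=target_gene, signature_name=gs.name
        )
        rows.append((gs.name, res.statistic, res.p_value, len(gs.genes)))
    screen = pd.DataFrame(rows, columns=["signature", "chi2", "p_value", "n_genes"])
    screen = screen.sort_values(["p_value", "signature"], kind="mergesort").reset_index(
        drop=True
    )
    top = screen["signature"].head(top_m).tolist()
    return top, screen


# ---------------------------------------------------------------------------
# Moderated differential expression
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    f = lambda y: special.polygamma(1, y) - x
    return float(brentq(f, 1e-8, 1e8))


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of a scaled-F prior to residual variances.

    Works on log variances: matches the mean and excess variance of
    ``log s^2`` against the digamma/trigamma moments implied by the
    scaled-F model, returning (prior df d0, prior variance s0^2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_de(
    matrix: ExpressionMatrix,
    assignment: GroupAssignment,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group differential expression.

    Per gene, the high-vs-low log2 fold-change is tested with a moderated
    t statistic: the pooled residual variance ``s_g^2`` (d_g df) is shrunk
    toward a prior (d0, s0^2) estimated by moment matching of the
    scaled-F distribution of the variances, and the statistic is referred
    to a t distribution with d0 + d_g df.  ``prior_df`` overrides the
    estimated d0 (0 reproduces the ordinary pooled-variance t test).

    Returns a DataFrame indexed by gene with ``log2fc``, ``p_value`` and
    Benjamini-Hochberg ``fdr`` columns.
    """
    from .downstream import bh_adjust

    high = assignment.samples_with("high")
    low = assignment.samples_with("low")
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"need >=2 samples per group, got high={len(high)}, low={len(low)}"
        )
    X1 = matrix.values[high].to_numpy()
    X2 = matrix.values[low].to_numpy()
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    logfc = m1 - m2

    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    elif np.isinf(prior_df):
        _, s0_sq = _fit_f_dist(s2, d)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2, d)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        total_df = d0 + d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(logfc)
    pos = se > 0
    t[pos] = logfc[pos] / se[pos]
    # zero SE: identical values in both groups -> t=0 (p=1) unless the
    # means still differ, which is a perfect separation -> p=0
    t[~pos] = np.where(logfc[~pos] == 0.0, 0.0, np.sign(logfc[~pos]) * np.inf)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {"log2fc": logfc, "p_value": p, "fdr": bh_adjust(p)}, index=matrix.values.index
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def merge_de_genes(
    de_tables: Sequence[pd.DataFrame],
    lfc_min: float = 1.0,
    fdr_max: float | None = 0.01,
    p_max: float | None = None,
    name: str = "merged_signature",
) -> GeneSet | EmptyGeneSet:
    """Union of upregulated genes passing thresholds in any DE table.

    A gene passes when ``log2fc > lfc_min`` and (``fdr < fdr_max`` or
    ``p_value < p_max``, whichever thresholds are given).  Gene order is
    sorted for determinism.
    """
    if not de_tables:
        raise ValueError("need at least one DE table")
    passing: set[str] = set()
    for table in de_tables:
        mask = table["log2fc"] > lfc_min
        if fdr_max is not None:
            mask &= table["fdr"] < fdr_max
        if p_max is not None:
            mask &= table["p_value"] < p_max
        passing |= set(table.index[mask])
    if not passing:
        return EmptyGeneSet(name)
    return GeneSet(name, tuple(sorted(passing)), provenance="merged DE genes")
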