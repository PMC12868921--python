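"""Downstream analyses: drug sensitivity, survival, pan-cancer correlation.

Drug response is modelled per drug as an ordinary least-squares fit of
log2 IC50 on the activity-group indicator adjusted for mutation status;
hits are enriched per target category with a hypergeometric test.
Survival comparisons use the k-group log-rank statistic (implemented
here) and proportional-hazards fits delegated to an established
partial-likelihood routine behind a fixed contract, with restricted cubic
splines for non-linear age effects.  Pan-cancer structure is summarized
by the Spearman correlation between cohort mean activity and pathway
mutation burden, and a density-based split into active and quiet cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .core import (
    ClinicalTable,
    DrugResponseTable,
    GroupAssignment,
    MutationTable,
)
from .scoring import IndexVector

# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Drug sensitivity
# ---------------------------------------------------------------------------


def drug_differential(
    drugs: DrugResponseTable,
    activity_groups: GroupAssignment,
    mutations: MutationTable | None = None,
    target_gene: str = "BRAF",
    min_per_group: int = 3,
    fdr_max: float = 0.05,
    delta_min: float = 1.0,
) -> pd.DataFrame:
    """Per-drug differential response between high and low activity lines.

    For every drug with complete IC50 in at least ``min_per_group`` cell
    lines per activity group, fit log2IC50 ~ intercept + high-indicator
    (+ mutant-indicator when a mutation table is supplied).  The group
    coefficient is the delta log2 IC50 (negative = more sensitive in the
    high-activity group); its two-sided t-test p-value is BH-adjusted
    across estimable drugs.  Hits require FDR < ``fdr_max`` and
    |delta| > ``delta_min``.  Collinear designs (group identical to
    mutation status) are flagged unestimable.
    """
    labels = activity_groups.labels[activity_groups.labels.isin(["high", "low"])]
    samples = [s for s in labels.index if s in drugs.ic50.columns]
    labels = labels.loc[samples]
    if mutations is not None:
        status = mutations.status_for(target_gene, samples)
        mut = (status == "mutant").astype(float)
    else:
        mut = None

    rows = []
    for drug in drugs.drug_ids:
        y_all = drugs.ic50.loc[drug, samples]
        ok = y_all.notna()
        y = y_all[ok].to_numpy(dtype=float)
        lab = labels[ok]
        n_high = int((lab == "high").sum())
        n_low = int((lab == "low").sum())
        if n_high < min_per_group or n_low < min_per_group:
            rows.append((drug, np.nan, np.nan, "skipped"))
            continue
        cols = [np.ones(len(y)), (lab == "high").to_numpy(dtype=float)]
        if mut is not None:
            cols.append(mut[ok.index[ok]].to_numpy())
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append((drug, np.nan, np.nan, "unestimable"))
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        if dof <= 0:
            rows.append((drug, np.nan, np.nan, "unestimable"))
            continue
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        delta = float(beta[1])
        if se == 0:
            p = 0.0 if delta != 0 else 1.0
        else:
            p = float(2.0 * stats.t.sf(abs(delta) / se, dof))
        rows.append((drug, delta, p, "ok"))

    table = pd.DataFrame(rows, columns=["drug_id", "delta_log2_ic50", "p_value", "fit"])
    table = table.set_index("drug_id")
    est = table["fit"] == "ok"
    fdr = pd.Series(np.nan, index=table.index)
    if est.any():
        fdr[est] = bh_adjust(table.loc[est, "p_value"].to_numpy())
    table["fdr"] = fdr
    table["direction"] = np.where(
        table["delta_log2_ic50"] < 0, "sensitive", "resistant"
    )
    table.loc[~est, "direction"] = ""
    table["hit"] = (
        est
        & (table["fdr"] < fdr_max)
        & (table["delta_log2_ic50"].abs() > delta_min)
    )
    table["target_category"] = [
        drugs.category_of(d) for d in table.index
    ]
    return table


def merge_screens(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine differential-response tables from multiple screens.

    A drug appearing in more than one screen keeps its most significant
    occurrence (smaller raw p-value); unestimable rows never win over
    estimable ones.
    """
    merged = pd.concat(tables)
    merged["_p_sort"] = merged["p_value"].fillna(np.inf)
    merged = merged.sort_values("_p_sort", kind="mergesort")
    merged = merged[~merged.index.duplicated(keep="first")]
    return merged.drop(columns="_p_sort").sort_index()


def category_enrichment(
    hits: Sequence[str],
    all_tested: Sequence[str],
    annotations: pd.Series,
) -> pd.DataFrame:
    """Hypergeometric over-representation of target categories among hits.

    Per category: population N = tested drugs, K = tested drugs in the
    category, n = hits drawn, observed overlap k; p = P(X >= k).  The
    categories' p-values are BH-adjusted.  An empty hit set gives p = 1
    everywhere.  Sensitive and resistant hit sets should be passed
    separately.
    """
    tested = list(dict.fromkeys(all_tested))
    hit_set = set(hits)
    stray = hit_set - set(tested)
    if stray:
        raise ValueError(f"hits not among tested drugs: {sorted(stray)[:5]}")
    cats = annotations.loc[tested]
    N, n = len(tested), len(hit_set)
    rows = []
    for cat in sorted(set(cats)):
        members = set(cats.index[cats == cat])
        K = len(members)
        k = len(members & hit_set)
        p = 1.0 if n == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, K, k, p))
    out = pd.DataFrame(rows, columns=["category", "n_category", "n_hits", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out.set_index("category")


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

TERTILE_VOCAB = ("low", "mid", "high")


def tertile_split(index: IndexVector | pd.Series) -> GroupAssignment:
    """Split samples at the 1/3 and 2/3 quantiles of the activity index;
    values on a boundary go to the lower group."""
    values = index.values if isinstance(index, IndexVector) else index
    if len(values) < 3:
        raise ValueError("need at least 3 samples for a tertile split")
    arr = values.to_numpy(dtype=float)
    if np.all(arr == arr[0]):
        raise ValueError("all index values identical; tertiles undefined")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    labels = np.where(arr <= q1, "low", np.where(arr <= q2, "mid", "high"))
    return GroupAssignment(pd.Series(labels, index=values.index), TERTILE_VOCAB)


def logrank_test(
    groups: GroupAssignment | pd.Series,
    clinical: ClinicalTable,
    endpoint: str = "os",
) -> tuple[float, float]:
    """K-group log-rank chi-square statistic and p-value (df = k-1).

    Standard observed-minus-expected form with the hypergeometric
    variance, which handles tied event times.  Requires at least one
    event; the statistic is invariant to a rescaling of the time unit.
    """
    labels = groups.labels if isinstance(groups, GroupAssignment) else groups
    df = clinical.table.set_index("sample_id")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    common = [s for s in labels.index if s in df.index]
    time = df.loc[common, tcol].to_numpy(dtype=float)
    event = df.loc[common, ecol].to_numpy(dtype=int)
    lab = labels.loc[common].to_numpy()
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    classes = sorted(set(lab.tolist()))
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two groups")
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_j = at_risk.sum()
        d_j = int(((time == t) & (event == 1)).sum())
        if n_j <= 1:
            continue
        n_ij = np.array([(at_risk & (lab == c)).sum() for c in classes], dtype=float)
        d_ij = np.array(
            [int(((time == t) & (event == 1) & (lab == c)).sum()) for c in classes],
            dtype=float,
        )
        O += d_ij
        E += d_j * n_ij / n_j
        frac = n_ij / n_j
        mult = d_j * (n_j - d_j) / (n_j - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(stats.chi2.sf(stat, k - 1))
    return stat, p


def rcs_basis(
    x: Sequence[float] | np.ndarray,
    n_knots: int = 3,
    knots: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Restricted (natural) cubic spline basis, linear beyond the
    boundary knots.

    Knots default to the 10th/50th/90th percentiles for three knots (the
    common convention; equally spaced percentile grids otherwise).  For
    k knots the basis has k-1 columns: the identity plus k-2 truncated
    cubic terms

        ((x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
         + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})) / (t_k-t_1)^2
    """
    arr = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots == 3:
            qs = [0.10, 0.50, 0.90]
        else:
            qs = np.linspace(0.05, 0.95, n_knots)
        knots = np.quantile(arr, qs)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(np.unique(arr)) < len(knots):
        raise ValueError("fewer distinct values than knots")
    if len(np.unique(knots)) < len(knots):
        raise ValueError("knots must be distinct")
    t = knots
    k = len(t)
    cols = {"x": arr}
    scale = (t[-1] - t[0]) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    for j in range(k - 2):
        term = (
            pos3(arr - t[j])
            - pos3(arr - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + pos3(arr - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / scale
        cols[f"spline_{j + 1}"] = term
    out = pd.DataFrame(cols)
    out.attrs["knots"] = tuple(float(v) for v in t)
    return out


@dataclass
class SurvivalResult:
    """Hazard ratios with confidence intervals and Wald p per model term,
    plus the model's log-rank comparison when groups were supplied."""

    terms: pd.DataFrame  # index term; columns hr, ci_low, ci_high, p
    logrank_stat: float | None = None
    logrank_p: float | None = None
    n: int = 0
    n_events: int = 0


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    alpha: float = 0.05,
) -> SurvivalResult:
    """Proportional-hazards fit via partial-likelihood maximization
    (established routine behind this contract).

    Returns per-term hazard ratios, Wald confidence intervals and
    p-values.  Warns when events are fewer than ten per parameter;
    non-convergence raises with the offending terms named.
    """
    data = df[[duration_col, event_col, *covariates]].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 10 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} parameters; "
            "estimates may be unstable"
        )
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox model failed to converge for terms {list(covariates)}: {err}"
        ) from err
    summ = cph.summary
    terms = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ[f"exp(coef) lower {100 * (1 - alpha):g}%"],
            "ci_high": summ[f"exp(coef) upper {100 * (1 - alpha):g}%"],
            "p": summ["p"],
            "coef": summ["coef"],
            "se": summ["se(coef)"],
        }
    )
    return SurvivalResult(terms=terms, n=len(data), n_events=n_events)


def cox_models(
    clinical: ClinicalTable,
    groups: GroupAssignment | None = None,
    mutations: MutationTable | None = None,
    target_gene: str = "BRAF",
    covariates: Sequence[str] = (),
    spline_age: bool = False,
    interaction: bool = False,
    endpoint: str = "os",
    mode: str = "multivariate",
    reference_group: str | None = None,
) -> SurvivalResult:
    """Survival models over activity groups, mutation status and clinical
    covariates.

    Builds the design matrix (group dummies against a reference level,
    mutant indicator, optional group x mutation interaction, optional
    3-knot restricted-cubic-spline age coding) and fits the Cox model; in
    ``univariate`` mode each term block is fit alone and the results
    concatenated.  A log-rank comparison across groups accompanies the
    fit when groups are given.
    """
    df = clinical.table.set_index("sample_id").copy()
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    design = pd.DataFrame(index=df.index)
    blocks: dict[str, list[str]] = {}

    if groups is not None:
        vocab = list(groups.vocabulary)
        ref = reference_group or vocab[0]
        lab = groups.labels.reindex(df.index)
        cols = []
        for level in vocab:
            if level == ref:
                continue
            col = f"group_{level}"
            design[col] = (lab == level).astype(float)
            cols.append(col)
        blocks["group"] = cols
    if mutations is not None:
        status = mutations.status_for(target_gene, list(df.index))
        design["mutant"] = (status == "mutant").astype(float)
        blocks["mutation"] = ["mutant"]
    if interaction:
        if groups is None or mutations is None:
            raise ValueError("interaction requires both groups and mutations")
        cols = []
        for gcol in blocks["group"]:
            col = f"{gcol}_x_mutant"
            design[col] = design[gcol] * design["mutant"]
            cols.append(col)
        blocks["interaction"] = cols
    for cov in covariates:
        if cov == "age" and spline_age:
            basis = rcs_basis(df["age"].to_numpy(), n_knots=3)
            design["age"] = basis["x"].to_numpy()
            design["age_spline_1"] = basis["spline_1"].to_numpy()
            blocks["age"] = ["age", "age_spline_1"]
        elif df[cov].dtype == object:
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True).astype(float)
            for c in dummies.columns:
                design[c] = dummies[c]
            blocks[cov] = list(dummies.columns)
        else:
            design[cov] = pd.to_numeric(df[cov])
            blocks[cov] = [cov]

    # empty factor levels yield all-zero dummies that break the fit
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant design columns: {constant}")
        design = design.drop(columns=constant)
        for cols in blocks.values():
            for c in constant:
                if c in cols:
                    cols.remove(c)
        blocks = {k: v for k, v in blocks.items() if v}

    full = pd.concat([df[[tcol, ecol]], design], axis=1)
    if mode == "multivariate":
        result = cox_fit(full, tcol, ecol, list(design.columns))
    elif mode == "univariate":
        parts = []
        for cols in blocks.values():
            res = cox_fit(full, tcol, ecol, cols)
            parts.append(res.terms)
        merged = pd.concat(parts)
        result = SurvivalResult(
            terms=merged, n=len(full.dropna()), n_events=int(full[ecol].sum())
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if groups is not None:
        stat, p = logrank_test(groups, clinical, endpoint=endpoint)
        result.logrank_stat, result.logrank_p = stat, p
    return result


# ---------------------------------------------------------------------------
# Pan-cancer
# ---------------------------------------------------------------------------


def pancancer_correlate(summaries: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between cohort mean activity index and
    pathway mutation ratio.

    ``summaries`` needs ``mean_index`` and ``mutation_ratio`` columns,
    one row per cohort (>= 4 cohorts); exact tie handling with a
    t-approximation p-value.
    """
    if len(summaries) < 4:
        raise ValueError("need at least 4 cohorts")
    x = summaries["mean_index"].to_numpy(dtype=float)
    y = summaries["mutation_ratio"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def active_quiet_split(
    mean_indices: pd.Series, grid_size: int = 512
) -> tuple[pd.Series, float]:
    """Split cohorts into active/quiet at the density antimode.

    A Gaussian kernel density (Silverman bandwidth) is fit to the cohort
    mean indices; the cut is the deepest local minimum between the two
    largest modes.  A unimodal density falls back to a median split with
    a warning.  The higher-mean group is labelled ``active``.
    Returns (labels, cut value).
    """
    if len(mean_indices) < 6:
        raise ValueError("need at least 6 cohorts for a density split")
    x = mean_indices.to_numpy(dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    maxima = [
        i
        for i in range(1, grid_size - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if len(maxima) < 2:
        warnings.warn("density is unimodal; falling back to a median split")
        cut = float(np.median(x))
        labels = np.where(x > cut, "active", "quiet")
    else:
        top_two = sorted(sorted(maxima, key=lambda i: dens[i])[-2:])
        left, right = top_two
        between = np.arange(left, right + 1)
        cut = float(grid[between[np.argmin(dens[between])]])
        labels = np.where(x > cut, "active", "quiet")
    return pd.Series(labels, index=mean_indices.index, name="activity_class"), cut
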