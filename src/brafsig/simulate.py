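"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: a cell-line
expression compendium with a planted activity signature, founder gene
sets mixing true and decoy genes, tumor/stroma-labelled single-cell
tables, survival cohorts with group-dependent hazards, and drug IC50
tables with a category-specific sensitivity shift.

All generators are pure functions of ``(config, seed)``.  A single
integer seed drives one named child stream per artifact, so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    ClinicalTable,
    DrugResponseTable,
    ExpressionMatrix,
    GeneSet,
    GroupAssignment,
    MutationTable,
)

# Fixed child-stream ids; never renumber (determinism contract).
_STREAMS = {
    "cellline": 11,
    "founders": 12,
    "scrna": 13,
    "survival": 14,
    "drugs": 15,
    "bags": 16,
    "external": 17,
}

DEFAULT_PATHWAY_GENES = (
    "KRAS", "EGFR", "ERBB2", "FGFR1", "FGFR2", "FGFR3",
    "HRAS", "NRAS", "ARAF", "RAF1", "RET", "KIT",
)


@dataclass
class ScrnaConfig:
    n_cells_per_type: int = 100
    cell_types: tuple[str, ...] = ("tumor", "fibroblast", "T", "B", "myeloid")
    tumor_dominance_shift: float = 2.0
    dominant_fraction: float = 0.8  # fraction of candidates made tumor-dominant
    noise_sd: float = 1.0


@dataclass
class SurvivalConfig:
    baseline_hazard: float = 1.0 / 365.0  # per day; median OS ~ 8.3 months
    hazard_ratios: dict = field(default_factory=dict)  # group label -> HR
    censoring_rate: float = 0.2


@dataclass
class DrugConfig:
    n_drugs: int = 60
    delta_log2_ic50: float = -2.0  # shift in the high-activity group
    noise_sd: float = 0.5
    category_sizes: dict = field(
        default_factory=lambda: {
            "ERK MAPK signaling": 8,
            "EGFR signaling": 6,
            "Apoptosis regulation": 8,
            "Cell cycle": 8,
            "DNA replication": 6,
            "Chromatin histone acetylation": 6,
        }
    )
    sensitive_category: str = "ERK MAPK signaling"


@dataclass
class SimulationConfig:
    """Knobs for the full synthetic bundle; the defaults are the study
    conditions every test and the acceptance run use."""

    seed: int
    n_genes: int = 2000
    n_samples: int = 200
    mutant_fraction: float = 0.25
    pathway_mutant_fraction: float = 0.15
    planted_signature_size: int = 25
    effect_size_log2: float = 2.0
    noise_sd: float = 0.5
    n_founder_sets: int = 8
    decoys_per_set: int = 10
    low_expr_per_set: int = 5
    mean_log2_range: tuple[float, float] = (4.0, 12.0)
    scrna: ScrnaConfig = field(default_factory=ScrnaConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    drugs: DrugConfig = field(default_factory=DrugConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("mutant_fraction", "pathway_mutant_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in ("n_genes", "n_samples", "planted_signature_size", "n_founder_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_signature_size > self.n_genes:
            raise ValueError(
                f"planted_signature_size {self.planted_signature_size} exceeds n_genes {self.n_genes}"
            )

    def rng(self, stream: str, index: int = 0) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream], int(index)])


class CellLineCohort(NamedTuple):
    expression: ExpressionMatrix
    mutations: MutationTable
    planted_genes: tuple[str, ...]
    low_expression_genes: tuple[str, ...]


def simulate_cellline_cohort(config: SimulationConfig) -> CellLineCohort:
    """Cell-line compendium with a planted activity signature.

    Gene baselines are Normal(mu_g, noise_sd) with mu_g ~ Uniform over
    ``mean_log2_range`` (so the mean > 6 expression filter removes a
    predictable fraction).  Mutant lines carry a ``+effect_size_log2``
    shift on the planted signature genes.  A configurable fraction of the
    non-mutant lines carry activating mutations in non-BRAF pathway genes
    (for exclusion tests).  Planted gene ids are returned as ground truth.
    """
    rng = config.rng("cellline")
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    samples = [f"CL{i:03d}" for i in range(config.n_samples)]

    lo, hi = config.mean_log2_range
    mu = rng.uniform(lo, hi, size=config.n_genes)

    # plant the signature among well-expressed genes so the biology is
    # detectable after the mean filter
    eligible = np.flatnonzero(mu > 6.5)
    if eligible.size < config.planted_signature_size:
        raise ValueError("too few well-expressed genes to plant the signature")
    planted_idx = rng.choice(eligible, size=config.planted_signature_size, replace=False)
    planted = tuple(genes[i] for i in sorted(planted_idx))

    n_mut = int(round(config.mutant_fraction * config.n_samples))
    mutant_mask = np.zeros(config.n_samples, dtype=bool)
    mutant_mask[rng.choice(config.n_samples, size=n_mut, replace=False)] = True

    values = rng.normal(mu[:, None], config.noise_sd, size=(config.n_genes, config.n_samples))
    rows = np.isin(np.arange(config.n_genes), planted_idx)
    values[np.ix_(rows, mutant_mask)] += config.effect_size_log2

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2")

    # mutation table: BRAF status for every line; non-BRAF pathway hits on
    # a fraction of the WT lines
    records = []
    variants = ["V600E"] * 9 + ["V600K"]
    for j, s in enumerate(samples):
        if mutant_mask[j]:
            records.append((s, "BRAF", "mutant", variants[rng.integers(len(variants))]))
        else:
            records.append((s, "BRAF", "WT", ""))
    wt_idx = np.flatnonzero(~mutant_mask)
    n_pw = int(round(config.pathway_mutant_fraction * config.n_samples))
    n_pw = min(n_pw, wt_idx.size)
    pw_idx = rng.choice(wt_idx, size=n_pw, replace=False)
    for j in pw_idx:
        gene = DEFAULT_PATHWAY_GENES[rng.integers(len(DEFAULT_PATHWAY_GENES))]
        records.append((samples[j], gene, "mutant", ""))
    mutations = MutationTable(
        pd.DataFrame(records, columns=["sample_id", "gene", "status", "variant"]),
        pathway_genes=("BRAF",) + DEFAULT_PATHWAY_GENES,
    )

    low_expr = tuple(g for g, m in zip(genes, mu) if m < 5.5)
    return CellLineCohort(expr, mutations, planted, low_expr)


def simulate_founder_signatures(
    config: SimulationConfig, cohort: CellLineCohort
) -> list[GeneSet]:
    """Founder gene sets: disjoint slices of the planted signature plus
    decoy background genes and a stated number of low-expression genes.

    Components are sampled without replacement across sets, so pairwise
    overlap is confined to the (disjoint) planted cores, i.e. zero.
    """
    rng = config.rng("founders")
    planted = list(cohort.planted_genes)
    background = [
        g
        for g in cohort.expression.gene_ids
        if g not in set(planted) and g not in set(cohort.low_expression_genes)
    ]
    low = list(cohort.low_expression_genes)

    k = config.n_founder_sets
    need_decoys = k * config.decoys_per_set
    need_low = k * config.low_expr_per_set
    if need_decoys > len(background) or need_low > len(low):
        raise ValueError("requested founder sizes exceed the gene universe")

    slices: list[list[str]] = [[] for _ in range(k)]
    order = rng.permutation(len(planted))
    for pos, gi in enumerate(order):
        slices[pos % k].append(planted[gi])
    decoy_pool = rng.choice(len(background), size=need_decoys, replace=False)
    low_pool = rng.choice(len(low), size=need_low, replace=False) if need_low else []

    sets = []
    for i in range(k):
        decoys = [background[j] for j in decoy_pool[i * config.decoys_per_set:(i + 1) * config.decoys_per_set]]
        lows = [low[j] for j in low_pool[i * config.low_expr_per_set:(i + 1) * config.low_expr_per_set]]
        genes = tuple(sorted(slices[i]) + decoys + lows)
        sets.append(GeneSet(name=f"founder_{i:02d}", genes=genes, provenance="synthetic founder"))
    return sets


class ScrnaTable(NamedTuple):
    values: pd.DataFrame  # genes x cells
    cell_labels: pd.Series  # cell -> type
    dominant_genes: tuple[str, ...]
    source: str = "scrna"


def simulate_scrna(
    config: SimulationConfig, candidate_genes: Sequence[str], dataset: int = 0
) -> ScrnaTable:
    """Cell-type-labelled expression with tumor-dominant candidates.

    A configured fraction of the candidates is shifted by
    ``tumor_dominance_shift`` in tumor cells only; the rest are expressed
    uniformly across compartments.  The ground-truth dominant set is
    returned (dominance order is by construction the candidate order
    restricted to the dominant set).
    """
    sc = config.scrna
    rng = config.rng("scrna", dataset)
    candidates = list(candidate_genes)
    n_dom = int(round(sc.dominant_fraction * len(candidates)))
    dom_idx = rng.choice(len(candidates), size=n_dom, replace=False) if n_dom else []
    dominant = tuple(candidates[i] for i in sorted(dom_idx))

    cells, labels = [], []
    for ct in sc.cell_types:
        for i in range(sc.n_cells_per_type):
            cells.append(f"{ct}_{i:04d}")
            labels.append(ct)
    labels = pd.Series(labels, index=cells, name="cell_type")

    base = rng.normal(2.0, sc.noise_sd, size=(len(candidates), len(cells)))
    tumor_mask = (labels == "tumor").to_numpy()
    rows = np.isin(np.arange(len(candidates)), dom_idx)
    base[np.ix_(rows, tumor_mask)] += sc.tumor_dominance_shift
    values = pd.DataFrame(base, index=candidates, columns=cells)
    return ScrnaTable(values, labels, dominant, source=f"scrna_{dataset}")


def simulate_survival(config: SimulationConfig, groups: GroupAssignment) -> ClinicalTable:
    """Exponential event times with hazard ``h0 * HR[group]`` and
    independent censoring tuned to the configured censoring fraction.

    Covariates: age ~ Normal(65, 10) truncated to [30, 90], sex balanced,
    stage categorical I-IV.
    """
    sv = config.survival
    rng = config.rng("survival")
    hrs = {}
    for label in groups.vocabulary:
        hr = sv.hazard_ratios.get(label, 1.0)
        if hr <= 0:
            raise ValueError(f"hazard ratio for {label!r} must be positive, got {hr}")
        hrs[label] = hr

    rows = []
    c = sv.censoring_rate
    for s, label in groups.labels.items():
        lam = sv.baseline_hazard * hrs[label]
        t_event = rng.exponential(1.0 / lam)
        if c > 0:
            mu_cens = lam * c / (1.0 - c)
            t_cens = rng.exponential(1.0 / mu_cens)
        else:
            t_cens = np.inf
        time = min(t_event, t_cens)
        event = int(t_event <= t_cens)
        age = float(np.clip(rng.normal(65.0, 10.0), 30.0, 90.0))
        sex = "F" if rng.random() < 0.5 else "M"
        stage = ["I", "II", "III", "IV"][rng.integers(4)]
        rows.append((s, max(time, 1e-6), event, age, sex, stage, label))
    df = pd.DataFrame(
        rows, columns=["sample_id", "os_time", "os_event", "age", "sex", "stage", "group"]
    )
    return ClinicalTable(df)


def simulate_drug_response(
    config: SimulationConfig,
    activity_groups: GroupAssignment,
    mutations: MutationTable | None = None,
) -> DrugResponseTable:
    """GDSC-style drug x cell-line log2 IC50 table.

    Drugs in the planted sensitive category have IC50 shifted by
    ``delta_log2_ic50`` in high-activity cell lines; all other drugs are
    null.  TARGET / TARGET_CATEGORY annotations are attached per drug.
    """
    dc = config.drugs
    rng = config.rng("drugs")
    sizes = dict(dc.category_sizes)
    total_annotated = sum(sizes.values())
    if total_annotated > dc.n_drugs:
        raise ValueError(
            f"category sizes sum to {total_annotated} > n_drugs {dc.n_drugs}"
        )
    if dc.sensitive_category not in sizes:
        raise ValueError(f"sensitive category {dc.sensitive_category!r} not in category_sizes")

    categories = []
    for cat, n in sizes.items():
        categories.extend([cat] * n)
    categories.extend(["unannotated"] * (dc.n_drugs - total_annotated))

    drugs = [f"drug_{i:03d}" for i in range(dc.n_drugs)]
    samples = activity_groups.sample_ids
    high = (activity_groups.labels == "high").to_numpy()

    base = rng.uniform(-2.0, 4.0, size=dc.n_drugs)
    values = rng.normal(base[:, None], dc.noise_sd, size=(dc.n_drugs, len(samples)))
    sens_rows = np.array([c == dc.sensitive_category for c in categories])
    values[np.ix_(sens_rows, high)] += dc.delta_log2_ic50

    ic50 = pd.DataFrame(values, index=drugs, columns=samples)
    ann = pd.DataFrame(
        {
            "target": [f"{c} target" for c in categories],
            "target_category": categories,
        },
        index=drugs,
    )
    return DrugResponseTable(ic50, ann)


class BagCohort(NamedTuple):
    expression: ExpressionMatrix
    bags: GroupAssignment
    signature_genes: tuple[str, ...]


def simulate_bag_cohort(
    config: SimulationConfig,
    n_samples: int = 400,
    n_signature_genes: int = 25,
    separation: float = 2.0,
    n_bags: int = 4,
    noise_sd: float = 1.5,
    stream: str = "bags",
) -> BagCohort:
    """Cohort with ``n_bags`` planted activity groups for classifier tests.

    Each group's signature-gene mean is offset by ``separation`` log2
    units from its neighbour; group sizes are balanced.  The within-group
    noise default keeps pairwise signature-gene correlations below the
    0.8 redundancy cutoff (between-group variance 5.0 vs within 2.25,
    expected |r| ~ 0.69), matching the reference analysis in which no
    signature gene was dropped as redundant.  Use ``stream='external'``
    for an independently drawn cohort from the same distribution
    (transfer tests).
    """
    rng = config.rng(stream)
    genes = [f"S{i:03d}" for i in range(n_signature_genes)]
    samples = [f"{stream.upper()}{i:04d}" for i in range(n_samples)]
    assignments = np.array([i % n_bags for i in range(n_samples)])
    assignments = rng.permutation(assignments)

    base = rng.uniform(5.0, 9.0, size=n_signature_genes)
    values = rng.normal(base[:, None], noise_sd, size=(n_signature_genes, n_samples))
    values += separation * assignments[None, :]

    vocab = tuple(f"BAG-{i}" for i in range(n_bags))
    labels = pd.Series([vocab[a] for a in assignments], index=samples)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2")
    return BagCohort(expr, GroupAssignment(labels, vocab), tuple(genes))
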