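"""End-to-end chains over the synthetic bundle.

Two composite workflows used by the test suite, the acceptance script and
the CLI: the signature-derivation chain (compendium -> founder screen ->
moderated DE -> rank aggregation -> stepwise panel) and the BAG transfer
chain (reference cohort -> feature selection -> RBF-SVM -> external
cohort).  Both are pure functions of a ``SimulationConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifier as clf
from . import derive
from . import panel as pm
from .core import ExpressionMatrix, GeneSet, zscore
from .panel import PanelSelectionTrace, RRAResult
from .simulate import (
    BagCohort,
    CellLineCohort,
    SimulationConfig,
    simulate_bag_cohort,
    simulate_cellline_cohort,
    simulate_founder_signatures,
    simulate_scrna,
)


@dataclass
class DerivationResult:
    cohort: CellLineCohort
    screen: pd.DataFrame
    top_signatures: list[str]
    merged: GeneSet
    rra: RRAResult
    aggregated: GeneSet
    trace: PanelSelectionTrace

    @property
    def planted_recovery(self) -> float:
        """Fraction of planted genes contained in the selected panel."""
        planted = set(self.cohort.planted_genes)
        return len(planted & set(self.trace.panel.genes)) / len(planted)

    @property
    def merged_recovery(self) -> float:
        planted = set(self.cohort.planted_genes)
        return len(planted & set(self.merged.genes)) / len(planted)


def derive_panel_chain(
    config: SimulationConfig,
    top_m: int = 5,
    de_preset: str = "methods",
    policy: str = "unclassified_penalized",
    n_scrna_datasets: int = 4,
    exclude_pathway_mutants: bool = True,
    loess_span: float = 0.5,
    min_mean: float = 6.0,
    max_panel_size: int | None = None,
) -> DerivationResult:
    """Run the full derivation chain on one synthetic bundle.

    Mirrors the compendium analysis: cell lines carrying activating
    mutations in non-BRAF pathway members are excluded; founder sets are
    immune-pruned and CV-filtered; the ``top_m`` most mutation-
    discriminative signatures are refined by moderated DE; the merged
    upregulated genes are ranked for tumor dominance in
    ``n_scrna_datasets`` single-cell datasets, aggregated by RRA
    (presence filter over the candidate universe), and grown into the
    final panel by stepwise selection under ``policy``.
    """
    cohort = simulate_cellline_cohort(config)
    matrix = cohort.expression
    if exclude_pathway_mutants:
        excluded = cohort.mutations.pathway_mutant_samples(exclude_gene="BRAF")
        keep = [s for s in matrix.sample_ids if s not in excluded]
        matrix = matrix.subset_samples(keep)

    founders = simulate_founder_signatures(config, cohort)
    blocklist = derive.load_default_blocklist()
    pruned = [derive.remove_immune_genes(gs, blocklist) for gs in founders]
    filtered = [
        derive.cv_filter(matrix, gs, loess_span=loess_span, min_mean=min_mean)
        for gs in pruned
        if len(gs.genes)
    ]
    filtered = [gs for gs in filtered if len(gs.genes)]

    top, screen = derive.screen_signatures(matrix, cohort.mutations, filtered, top_m=top_m)
    by_name = {gs.name: gs for gs in filtered}
    thresholds = derive.DE_PRESETS[de_preset]
    de_tables = []
    for name in top:
        assignment = derive.stratify_by_signature(matrix, by_name[name], k=3)
        de_tables.append(derive.moderated_de(matrix, assignment))
    merged = derive.merge_de_genes(de_tables, **thresholds)
    if not merged.genes:
        raise RuntimeError("derivation produced an empty merged signature")

    lists = []
    for d in range(n_scrna_datasets):
        sc = simulate_scrna(config, list(merged.genes), dataset=d)
        lists.append(pm.tumor_dominance_ranking(sc, list(merged.genes)))
    rra = pm.rra_aggregate(lists)
    # presence filter: keep every candidate seen in a list, in aggregate
    # order (the score-threshold alternative is too strict for small
    # candidate universes, where normalized ranks cannot be extreme)
    aggregated = pm.select_aggregated_genes(rra, score_max=np.inf, name="aggregated")
    usable = [g for g in aggregated.genes if g in matrix.values.index]
    trace = pm.stepwise_panel(
        usable,
        matrix,
        cohort.mutations,
        max_size=max_panel_size or len(usable),
        policy=policy,
        panel_name="selected_panel",
    )
    return DerivationResult(
        cohort=cohort,
        screen=screen,
        top_signatures=top,
        merged=merged,
        rra=rra,
        aggregated=aggregated,
        trace=trace,
    )


@dataclass
class TransferResult:
    model: clf.ClassifierModel
    test_report: dict
    external_accuracy: float
    reference: BagCohort
    external: BagCohort

    @property
    def test_accuracy(self) -> float:
        return float(self.test_report["accuracy"])


def bag_transfer_chain(
    config: SimulationConfig,
    n_samples: int = 400,
    separation: float = 2.0,
    n_bags: int = 4,
    folds: int = 5,
    max_features: int | None = 10,
    train_frac: float = 0.8,
) -> TransferResult:
    """Train the BAG transfer classifier on a planted reference cohort
    and apply it to an independently simulated external cohort.

    The chain is the full stack: per-gene z-scoring, stratified 80/20
    split, correlation redundancy filter, random-forest importance
    ranking, stepwise RBF-SVM with cross-validated tuning, held-out
    evaluation, and external-cohort label recovery.
    """
    ref = simulate_bag_cohort(
        config, n_samples=n_samples, separation=separation, n_bags=n_bags, stream="bags"
    )
    zs = zscore(ref.expression, "gene")
    labels = ref.bags.labels
    train_ids, test_ids = clf.stratified_partition(labels, train_frac, seed=config.seed)
    train = zs.subset_samples(train_ids)
    retained = clf.redundancy_filter(train, cutoff=0.8)
    ranked = clf.rank_features_rf(
        train.subset_genes(retained), labels.loc[train_ids], seed=config.seed
    )
    model = clf.stepwise_svm(
        train,
        ranked,
        labels.loc[train_ids],
        folds=folds,
        seed=config.seed,
        max_features=max_features,
    )
    report = clf.evaluate_model(model, zs.subset_samples(test_ids), labels.loc[test_ids])

    ext = simulate_bag_cohort(
        config, n_samples=n_samples, separation=separation, n_bags=n_bags,
        stream="external",
    )
    ext_z = zscore(ext.expression, "gene")
    predicted = clf.apply_model(model, ext_z)
    agreement = float((predicted.labels == ext.bags.labels).mean())
    return TransferResult(
        model=model,
        test_report=report,
        external_accuracy=agreement,
        reference=ref,
        external=ext,
    )
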