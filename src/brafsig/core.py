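"""Core domain types and table IO for the BRAF activity pipeline.

The pipeline moves five kinds of tables around: expression matrices
(genes x samples on a declared scale), gene sets (GMT), per-sample
mutation calls, clinical/survival tables, and drug response (IC50)
tables.  Everything here validates on construction so downstream
stages can assume identifiers are unique and values finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXPRESSION_SCALES = ("log2", "vst", "zscore_gene", "zscore_sample", "raw")
MUTATION_STATUSES = ("mutant", "WT", "unknown")


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


class ParseError(ValueError):
    """A file could not be parsed into the expected table shape."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    scale
        One of ``log2``, ``vst``, ``zscore_gene``, ``zscore_sample``, ``raw``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValidationError(
                f"unknown expression scale {self.scale!r}; expected one of {EXPRESSION_SCALES}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr.astype(float))):
            bad = np.argwhere(~np.isfinite(arr.astype(float)))
            g, s = bad[0]
            raise ValidationError(
                f"non-finite value at gene {self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.scale)


def read_expression(
    path: str | Path,
    scale: str = "log2",
    sep: str = "\t",
    collapse_duplicates: bool = False,
) -> ExpressionMatrix:
    """Read a headered genes-x-samples table (first column = gene ids).

    Duplicate gene rows are an error unless ``collapse_duplicates`` is set,
    in which case duplicated rows are averaged per sample.  Missing or
    non-numeric cells are rejected with the offending cell named.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(
                f"non-numeric cell at gene {bad[0]!r}, sample {col!r} in {path}"
            )
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        sample = df.columns[df.isna().any(axis=0)][0]
        raise ParseError(f"missing value at gene {gene!r}, sample {sample!r} in {path}")
    if df.index.has_duplicates:
        if not collapse_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(
                f"duplicate gene ids {dupes[:5]} in {path}; pass collapse_duplicates=True to average"
            )
        return collapse_duplicate_genes(df, scale=scale)
    return ExpressionMatrix(df, scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, float_format="%.12g")


def collapse_duplicate_genes(
    values: pd.DataFrame | ExpressionMatrix, scale: str = "log2"
) -> ExpressionMatrix:
    """Average rows sharing a gene id (probe-level collapse).

    Each duplicated gene id is replaced by the arithmetic mean of its rows,
    per sample.  Idempotent; first-occurrence row order is preserved.
    """
    if isinstance(values, ExpressionMatrix):
        scale = values.scale
        values = values.values
    collapsed = values.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed, scale)


def zscore(matrix: ExpressionMatrix, axis: str = "gene") -> ExpressionMatrix:
    """Standardize per gene (across samples) or per sample (across genes).

    Uses the sample standard deviation (n-1 denominator).  Zero-variance
    units make standardization undefined and raise ``ValidationError``
    listing the offending ids.
    """
    if axis not in ("gene", "sample"):
        raise ValueError(f"axis must be 'gene' or 'sample', got {axis!r}")
    df = matrix.values
    if axis == "gene":
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        zero = sd[sd == 0].index.tolist()
        if zero:
            raise ValidationError(f"zero-variance genes cannot be z-scored: {zero[:10]}")
        out = df.sub(mu, axis=0).div(sd, axis=0)
        return ExpressionMatrix(out, "zscore_gene")
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance samples cannot be z-scored: {zero[:10]}")
    out = df.sub(mu, axis=1).div(sd, axis=1)
    return ExpressionMatrix(out, "zscore_sample")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be nonempty")
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are dropped (first occurrence kept) with
    a warning; a line with fewer than three fields is a parse error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            dupes = []
            for g in genes:
                if g in seen:
                    dupes.append(g)
                else:
                    seen[g] = None
            if dupes:
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} listed duplicate genes {sorted(set(dupes))}; deduplicated"
                )
            sets.append(GeneSet(name=name, genes=tuple(seen), provenance=desc))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.provenance or "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------


@dataclass
class MutationTable:
    """Long-format per-sample, per-gene mutation calls.

    ``table`` columns: ``sample_id``, ``gene``, ``status`` in
    {mutant, WT, unknown}, optional ``variant`` label (e.g. V600E).
    Samples absent from the table for a gene default to WT when queried.
    """

    table: pd.DataFrame
    pathway_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "status"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"mutation table missing columns {sorted(missing)}")
        bad = set(self.table["status"]) - set(MUTATION_STATUSES)
        if bad:
            raise ValidationError(f"unknown mutation statuses {sorted(bad)}")
        if self.table.duplicated(["sample_id", "gene"]).any():
            dupes = self.table[self.table.duplicated(["sample_id", "gene"])]
            raise ValidationError(
                f"sample/gene pairs repeated: {dupes[['sample_id', 'gene']].values[:3].tolist()}"
            )
        self.pathway_genes = tuple(self.pathway_genes)

    def status_for(
        self, gene: str, sample_ids: Sequence[str], default: str = "WT"
    ) -> pd.Series:
        """Per-sample status for one gene; unrecorded samples get ``default``."""
        sub = self.table[self.table["gene"] == gene].set_index("sample_id")["status"]
        return pd.Series(
            [sub.get(s, default) for s in sample_ids], index=list(sample_ids), name=gene
        )

    def variant_for(self, gene: str, sample_ids: Sequence[str]) -> pd.Series:
        if "variant" not in self.table.columns:
            return pd.Series([""] * len(sample_ids), index=list(sample_ids), name=gene)
        sub = self.table[self.table["gene"] == gene].set_index("sample_id")["variant"]
        return pd.Series(
            [sub.get(s, "") for s in sample_ids], index=list(sample_ids), name=gene
        )

    def pathway_mutant_samples(self, exclude_gene: str = "BRAF") -> set[str]:
        """Samples mutant in any pathway gene other than ``exclude_gene``."""
        genes = [g for g in self.pathway_genes if g != exclude_gene]
        mask = self.table["gene"].isin(genes) & (self.table["status"] == "mutant")
        return set(self.table.loc[mask, "sample_id"])


def read_mutations(
    path: str | Path, pathway_genes: Sequence[str] = (), sep: str = "\t"
) -> MutationTable:
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    return MutationTable(df, tuple(pathway_genes))


def write_mutations(mutations: MutationTable, path: str | Path, sep: str = "\t") -> None:
    cols = ["sample_id", "gene", "status"] + (
        ["variant"] if "variant" in mutations.table.columns else []
    )
    mutations.table[cols].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and covariates.

    Requires ``sample_id``, ``os_time`` (days, > 0), ``os_event`` (0/1);
    optional ``pfs_time``/``pfs_event`` and arbitrary covariate columns
    (age, sex, stage, ...).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "os_time", "os_event"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        times = pd.to_numeric(self.table["os_time"])
        if (times <= 0).any():
            bad = self.table.loc[times <= 0, "sample_id"].tolist()
            raise ValidationError(f"non-positive os_time for samples {bad[:5]}")
        events = set(pd.to_numeric(self.table["os_event"]))
        if not events <= {0, 1}:
            raise ValidationError(f"os_event must be 0/1, got {sorted(events)}")
        for prefix in ("pfs",):
            tcol, ecol = f"{prefix}_time", f"{prefix}_event"
            if tcol in self.table.columns:
                sub = self.table[tcol].dropna()
                if (pd.to_numeric(sub) <= 0).any():
                    raise ValidationError(f"non-positive {tcol}")
                ev = set(pd.to_numeric(self.table.loc[sub.index, ecol].dropna()))
                if not ev <= {0, 1}:
                    raise ValidationError(f"{ecol} must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


def read_clinical(path: str | Path, sep: str = "\t") -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep=sep))


def write_clinical(clinical: ClinicalTable, path: str | Path, sep: str = "\t") -> None:
    clinical.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Drug response tables
# ---------------------------------------------------------------------------


@dataclass
class DrugResponseTable:
    """Drug x cell-line log2 IC50 values plus per-drug target annotations.

    ``ic50``: DataFrame indexed by drug id, columns cell-line ids; NaN marks
    an unmeasured pair (complete-case per drug downstream).  ``annotations``:
    DataFrame indexed by drug id with ``target`` and ``target_category``
    columns; unannotated drugs must carry the explicit label
    ``"unannotated"``.
    """

    ic50: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ic50.index.has_duplicates:
            raise ValidationError("duplicate drug ids in IC50 table")
        arr = self.ic50.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("infinite IC50 values")
        missing_ann = set(self.ic50.index) - set(self.annotations.index)
        if missing_ann:
            raise ValidationError(
                f"drugs without annotation rows: {sorted(missing_ann)[:5]}"
            )
        for col in ("target", "target_category"):
            if col not in self.annotations.columns:
                raise ValidationError(f"annotations missing column {col!r}")
        if (self.annotations["target_category"].fillna("") == "").any():
            raise ValidationError(
                'empty target_category; use the explicit label "unannotated"'
            )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.ic50.index)

    def category_of(self, drug: str) -> str:
        return str(self.annotations.loc[drug, "target_category"])


def read_drug_response(
    ic50_path: str | Path, annotation_path: str | Path, sep: str = "\t"
) -> DrugResponseTable:
    ic50 = pd.read_csv(ic50_path, sep=sep, index_col=0)
    ann = pd.read_csv(annotation_path, sep=sep, index_col=0)
    return DrugResponseTable(ic50, ann)


def write_drug_response(
    drugs: DrugResponseTable, ic50_path: str | Path, annotation_path: str | Path,
    sep: str = "\t",
) -> None:
    out = drugs.ic50.copy()
    out.index.name = "drug_id"
    out.to_csv(ic50_path, sep=sep, float_format="%.12g")
    ann = drugs.annotations.copy()
    ann.index.name = "drug_id"
    ann.to_csv(annotation_path, sep=sep)


# ---------------------------------------------------------------------------
# Group assignments and classification counts
# ---------------------------------------------------------------------------

THREE_GROUP_VOCAB = ("low", "unclassified", "high")


def bag_vocabulary(k: int) -> tuple[str, ...]:
    return tuple(f"BAG-{i}" for i in range(k))


@dataclass
class GroupAssignment:
    """Sample -> label map over an ordered label vocabulary."""

    labels: pd.Series  # index sample_id, values labels
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        self.vocabulary = tuple(self.vocabulary)
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValidationError("vocabulary labels must be unique")
        extra = set(self.labels) - set(self.vocabulary)
        if extra:
            raise ValidationError(f"labels outside vocabulary: {sorted(extra)}")
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicate sample ids in group assignment")
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def samples_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def restrict(self, labels: Sequence[str]) -> "GroupAssignment":
        keep = self.labels[self.labels.isin(labels)]
        return GroupAssignment(keep, self.vocabulary)


def read_groups(path: str | Path, vocabulary: Sequence[str], sep: str = "\t") -> GroupAssignment:
    df = pd.read_csv(path, sep=sep)
    return GroupAssignment(df.set_index("sample_id")["label"], tuple(vocabulary))


def write_groups(groups: GroupAssignment, path: str | Path, sep: str = "\t") -> None:
    out = groups.labels.rename("label").rename_axis("sample_id").reset_index()
    out.to_csv(path, sep=sep, index=False)


@dataclass
class ClassificationCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name.upper()} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn
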