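"""Ingestion of cBioPortal-style study tables into a :class:`CohortDataset`.

Covers the standard preprocessing for pan-cancer AD/SCC cohorts: collapsing
MAF-like mutation records to a per-gene presence/absence matrix (1 = at
least one non-synonymous mutation), restricting genes to a curated cancer
gene list (Cancer Gene Census), keeping primary-tumor samples present in
both the mutation and expression modality, and dropping samples with
incomplete data. Expression values are expected as z-scores; a
standardization fallback is provided for raw matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, NamedTuple

import numpy as np
import pandas as pd

from .cohort import AD, SCC, CohortDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "GeneFilter",
    "NONSYNONYMOUS_CLASSES",
    "binarize_mutations",
    "apply_filters",
    "zscore_expression",
    "read_maf",
    "read_gene_list",
    "read_cohort",
    "cohort_to_frames",
]

#: Standard MAF consequence classes counted as non-synonymous.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)


class MutationRecord(NamedTuple):
    sample_id: str
    gene_symbol: str
    variant_classification: str


@dataclass(frozen=True)
class GeneFilter:
    """A curated gene universe (e.g. the COSMIC Cancer Gene Census)."""

    allowed_genes: frozenset[str]
    version_tag: str = ""

    def __post_init__(self):
        if not self.allowed_genes:
            raise ValueError("GeneFilter.allowed_genes must be nonempty")


def binarize_mutations(
    records: Iterable[MutationRecord],
    samples: list[str],
    genes: list[str],
    nonsynonymous_classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
) -> np.ndarray:
    """Presence/absence matrix over (samples, genes).

    An entry is 1 iff at least one record for that (sample, gene) pair has a
    variant classification in ``nonsynonymous_classes``; repeated hits do not
    accumulate. Records for unknown samples or genes are skipped with a
    logged count.
    """
    if not samples or not genes:
        raise ValueError("samples and genes must be nonempty")
    sample_pos = {s: i for i, s in enumerate(samples)}
    gene_pos = {g: j for j, g in enumerate(genes)}
    matrix = np.zeros((len(samples), len(genes)), dtype=np.uint8)
    n_records = n_skipped = 0
    for rec in records:
        n_records += 1
        if rec.variant_classification not in nonsynonymous_classes:
            continue
        i = sample_pos.get(rec.sample_id)
        j = gene_pos.get(rec.gene_symbol)
        if i is None or j is None:
            n_skipped += 1
            continue
        matrix[i, j] = 1
    if n_records == 0:
        logger.warning("binarize_mutations: no mutation records supplied")
    if n_skipped:
        logger.warning(
            "binarize_mutations: skipped %d records for unknown samples/genes",
            n_skipped,
        )
    return matrix


def default_primary_tumor_predicate(sample_id: str) -> bool:
    """TCGA convention: primary-tumor sample barcodes end in the '-01' code."""
    return sample_id.endswith("-01")


def apply_filters(
    mutation_data: pd.DataFrame,
    expression_data: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_filter: GeneFilter | None = None,
    primary_tumor_predicate: Callable[[str], bool] | None = default_primary_tumor_predicate,
    lung_tissue_label: str = "lung",
) -> CohortDataset:
    """Intersect modalities, apply sample/gene filters and build a cohort.

    ``mutation_data`` and ``expression_data`` are sample-by-gene frames
    (mutations binary). ``annotations`` needs columns ``sample_id``,
    ``histology`` (AD/SCC) and ``tissue``; optional ``pfs_time``/
    ``pfs_event``. Retains primary-tumor AD/SCC samples present in both
    modalities, restricts genes to ``gene_filter`` intersected with the
    genes present in both modalities, then drops samples with any missing
    value among the retained genes.
    """
    ann = annotations.set_index("sample_id") if "sample_id" in annotations else annotations
    steps: list[tuple[str, int]] = []

    samples = [s for s in ann.index if s in mutation_data.index]
    steps.append(("missing mutation data", len(ann) - len(samples)))
    n0 = len(samples)
    samples = [s for s in samples if s in expression_data.index]
    steps.append(("missing expression data", n0 - len(samples)))
    n0 = len(samples)
    samples = [s for s in samples if ann.loc[s, "histology"] in (AD, SCC)]
    steps.append(("non-AD/SCC histology", n0 - len(samples)))
    if primary_tumor_predicate is not None:
        n0 = len(samples)
        samples = [s for s in samples if primary_tumor_predicate(s)]
        steps.append(("non-primary tumor", n0 - len(samples)))
    if not samples:
        raise ValueError("no samples remain after sample filtering")

    genes = [g for g in mutation_data.columns if g in set(expression_data.columns)]
    if gene_filter is not None:
        genes = [g for g in genes if g in gene_filter.allowed_genes]
    if not genes:
        raise ValueError("no genes remain after gene filtering")

    mut = mutation_data.loc[samples, genes]
    expr = expression_data.loc[samples, genes]
    complete = ~(mut.isna().any(axis=1) | expr.isna().any(axis=1))
    steps.append(("incomplete data", int((~complete).sum())))
    mut, expr = mut[complete.values], expr[complete.values]
    samples = list(mut.index)
    if not samples:
        raise ValueError("no samples remain after completeness filtering")

    for step, removed in steps:
        if removed:
            logger.info("apply_filters: removed %d samples (%s)", removed, step)

    ann = ann.loc[samples]
    tissue = ann["tissue"].to_numpy(dtype=object)
    has_surv = "pfs_time" in ann.columns and "pfs_event" in ann.columns
    return CohortDataset(
        mutation_matrix=mut.to_numpy(dtype=np.uint8),
        expression_matrix=expr.to_numpy(dtype=float),
        sample_ids=samples,
        gene_ids=genes,
        histology=ann["histology"].to_numpy(dtype=object),
        tissue=tissue,
        is_lung=np.asarray([t == lung_tissue_label for t in tissue]),
        pfs_time=ann["pfs_time"].to_numpy(dtype=float) if has_surv else None,
        pfs_event=ann["pfs_event"].to_numpy(dtype=int) if has_surv else None,
        lung_tissue_label=lung_tissue_label,
    )


def zscore_expression(
    raw_expression: pd.DataFrame, mode: str = "passthrough"
) -> pd.DataFrame:
    """Per-gene standardization (sample SD, ddof=1) or identity pass-through.

    cBioPortal archives already ship RSEM z-scores, so pass-through is the
    default; the fallback standardizes raw values and drops zero-variance
    genes with a warning.
    """
    if mode == "passthrough":
        return raw_expression
    if mode != "fallback":
        raise ValueError(f"unknown mode {mode!r}")
    mean = raw_expression.mean(axis=0)
    sd = raw_expression.std(axis=0, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        logger.warning(
            "zscore_expression: dropping %d zero-variance genes", int(degenerate.sum())
        )
    keep = raw_expression.columns[~degenerate]
    return (raw_expression[keep] - mean[keep]) / sd[keep]


# ---------------------------------------------------------------------------
# readers

def read_maf(path) -> list[MutationRecord]:
    """Read a cBioPortal `data_mutations.txt`-style tab-delimited table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF table missing columns: {sorted(missing)}")
    return [
        MutationRecord(row.Tumor_Sample_Barcode, row.Hugo_Symbol, row.Variant_Classification)
        for row in df.itertuples()
    ]


def read_gene_list(path) -> GeneFilter:
    """Gene universe from one-symbol-per-line text or a CSV with a
    Gene-Symbol-like column."""
    path = Path(path)
    text = path.read_text()
    if "," in text.splitlines()[0]:
        df = pd.read_csv(path)
        col = next(
            (c for c in df.columns if c.lower().replace(" ", "-") in
             ("gene-symbol", "gene_symbol", "hugo_symbol")),
            df.columns[0],
        )
        genes = [str(g) for g in df[col].dropna()]
    else:
        genes = [line.strip() for line in text.splitlines() if line.strip()]
    return GeneFilter(frozenset(genes), version_tag=path.stem)


def read_cohort(indir) -> CohortDataset:
    """Read back the TSV files produced by :func:`synthetic.write_cohort`."""
    indir = Path(indir)
    mut = pd.read_csv(indir / "mutations.tsv", sep="\t", index_col="sample_id")
    expr = pd.read_csv(
        indir / "expression.tsv", sep="\t", index_col="sample_id",
        float_precision="round_trip",
    )
    ann = pd.read_csv(indir / "samples.tsv", sep="\t", float_precision="round_trip")
    has_surv = "pfs_time" in ann.columns
    tissue = ann["tissue"].to_numpy(dtype=object)
    # the lung label is whichever tissue the is_lung column flags
    lung_rows = ann["is_lung"].astype(bool).to_numpy()
    lung_label = str(tissue[lung_rows][0]) if lung_rows.any() else "lung"
    return CohortDataset(
        mutation_matrix=mut.to_numpy(dtype=np.uint8),
        expression_matrix=expr.to_numpy(dtype=float),
        sample_ids=list(mut.index),
        gene_ids=list(mut.columns),
        histology=ann["histology"].to_numpy(dtype=object),
        tissue=tissue,
        is_lung=lung_rows,
        pfs_time=ann["pfs_time"].to_numpy(dtype=float) if has_surv else None,
        pfs_event=ann["pfs_event"].to_numpy(dtype=int) if has_surv else None,
        lung_tissue_label=lung_label,
    )


def cohort_to_frames(data: CohortDataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Decompose a cohort into (mutation, expression, annotation) frames, the
    inverse of :func:`apply_filters` for an already-clean cohort."""
    mut = pd.DataFrame(data.mutation_matrix, index=data.sample_ids, columns=data.gene_ids)
    expr = pd.DataFrame(data.expression_matrix, index=data.sample_ids, columns=data.gene_ids)
    ann = pd.DataFrame(
        {
            "sample_id": data.sample_ids,
            "histology": data.histology,
            "tissue": data.tissue,
        }
    )
    if data.pfs_time is not None:
        ann["pfs_time"] = data.pfs_time
        ann["pfs_event"] = data.pfs_event
    return mut, expr, ann
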