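"""Aligned multi-omics cohort container.

A :class:`CohortDataset` holds a binary somatic-mutation matrix (1 = the
sample carries at least one non-synonymous mutation in the gene) and a dense
expression z-score matrix over the same samples and genes, plus per-sample
histology (AD vs. SCC), tissue and optional progression-free-survival
annotations. Every downstream stage — model training, cross-validation,
ensembling, attribution — consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CohortDataset", "AD", "SCC"]

AD = "AD"
SCC = "SCC"


@dataclass
class CohortDataset:
    """Sample-by-gene mutation and expression matrices with annotations.

    Both matrices share the same sample ordering (rows) and gene ordering
    (columns); this is validated at construction. ``histology`` uses the
    pan-tissue labels ``"AD"``/``"SCC"``; lung samples are the NSCLC subset
    (AD = LUAD, SCC = LUSC).
    """

    mutation_matrix: np.ndarray
    expression_matrix: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    histology: np.ndarray
    tissue: np.ndarray
    is_lung: np.ndarray
    pfs_time: np.ndarray | None = None
    pfs_event: np.ndarray | None = None
    lung_tissue_label: str = field(default="lung", repr=False)

    def __post_init__(self) -> None:
        self.mutation_matrix = np.asarray(self.mutation_matrix)
        self.expression_matrix = np.asarray(self.expression_matrix, dtype=float)
        self.histology = np.asarray(self.histology, dtype=object)
        self.tissue = np.asarray(self.tissue, dtype=object)
        self.is_lung = np.asarray(self.is_lung, dtype=bool)
        n, g = self.mutation_matrix.shape
        if self.expression_matrix.shape != (n, g):
            raise ValueError(
                f"matrix shapes differ: mutation {self.mutation_matrix.shape} "
                f"vs expression {self.expression_matrix.shape}"
            )
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match matrix rows")
        if len(self.gene_ids) != g or len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique and match matrix columns")
        if not np.isin(self.mutation_matrix, (0, 1)).all():
            raise ValueError("mutation_matrix entries must be 0/1")
        if np.isnan(self.expression_matrix).any():
            raise ValueError("expression_matrix contains missing values")
        bad = set(self.histology) - {AD, SCC}
        if bad:
            raise ValueError(f"unknown histology labels: {sorted(bad)}")
        expected_lung = np.asarray(
            [t == self.lung_tissue_label for t in self.tissue], dtype=bool
        )
        if not np.array_equal(expected_lung, self.is_lung):
            raise ValueError("is_lung inconsistent with tissue labels")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.mutation_matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.mutation_matrix.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Binary labels, 1 = AD/LUAD (the positive class), 0 = SCC/LUSC."""
        return (self.histology == AD).astype(float)

    @property
    def is_nsclc(self) -> np.ndarray:
        """Lung samples; AD = LUAD and SCC = LUSC within this subset."""
        return self.is_lung

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in cohort") from None

    def subset(self, idx: np.ndarray) -> "CohortDataset":
        """Row-subset preserving alignment of every field."""
        idx = np.asarray(idx)
        return CohortDataset(
            mutation_matrix=self.mutation_matrix[idx],
            expression_matrix=self.expression_matrix[idx],
            sample_ids=[self.sample_ids[i] for i in np.arange(self.n_samples)[idx]]
            if idx.dtype == bool
            else [self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            histology=self.histology[idx],
            tissue=self.tissue[idx],
            is_lung=self.is_lung[idx],
            pfs_time=None if self.pfs_time is None else self.pfs_time[idx],
            pfs_event=None if self.pfs_event is None else self.pfs_event[idx],
            lung_tissue_label=self.lung_tissue_label,
        )

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.asarray([pos[s] for s in sample_ids], dtype=int)

    def equals(self, other: "CohortDataset") -> bool:
        """Bit-exact equality of matrices and annotations."""
        same = (
            np.array_equal(self.mutation_matrix, other.mutation_matrix)
            and np.array_equal(self.expression_matrix, other.expression_matrix)
            and self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.histology, other.histology)
            and np.array_equal(self.tissue, other.tissue)
            and np.array_equal(self.is_lung, other.is_lung)
        )
        for a, b in ((self.pfs_time, other.pfs_time), (self.pfs_event, other.pfs_event)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return same
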