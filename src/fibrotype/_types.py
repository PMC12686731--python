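"""Core in-memory containers shared across pipeline stages.

The central object is :class:`CellCohort`, a genes-by-cells sparse count
matrix with aligned per-cell and per-gene metadata.  Gene sets are plain
``dict[str, list[str]]`` collections read from / written to GMT.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_META_COLUMNS = ("sample", "tissue", "condition", "batch", "age_group")


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected layout."""


class InvalidConfigError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


@dataclass
class CellCohort:
    """Sparse nonnegative count matrix (genes x cells) with aligned metadata.

    Parameters
    ----------
    counts
        CSR matrix of raw counts, shape ``(n_genes, n_cells)``.
    gene_ids
        Unique, case-sensitive gene symbols, one per row.
    cell_meta
        One record per column; indexed by ``cell_id`` with at least the
        columns in :data:`CELL_META_COLUMNS` (missing ones are added as NA).
    normalized
        Optional dense log1p(CP10K) matrix filled in by
        :func:`fibrotype.qc.normalize_log`; same shape as ``counts``.
    flags
        Named per-cell boolean vectors (QC and consensus decisions).
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_meta: pd.DataFrame
    normalized: np.ndarray | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if (self.counts.data < 0).any():
            raise FormatError("counts must be nonnegative")
        self.gene_ids = pd.Index(self.gene_ids)
        if self.gene_ids.has_duplicates:
            raise FormatError("gene_ids must be unique after ingestion")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[0]} rows"
            )
        if len(self.cell_meta) != self.counts.shape[1]:
            raise FormatError(
                f"{len(self.cell_meta)} cell records for "
                f"{self.counts.shape[1]} columns"
            )
        self.cell_meta = self.cell_meta.copy()
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = pd.NA

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def subset(
        self,
        gene_mask: np.ndarray | None = None,
        cell_mask: np.ndarray | None = None,
    ) -> "CellCohort":
        """Return a new cohort restricted to the masked genes/cells."""
        gm = np.asarray(gene_mask if gene_mask is not None else np.ones(self.n_genes, bool))
        cm = np.asarray(cell_mask if cell_mask is not None else np.ones(self.n_cells, bool))
        sub = CellCohort(
            counts=self.counts[gm][:, cm].tocsr(),
            gene_ids=self.gene_ids[gm],
            cell_meta=self.cell_meta.loc[cm],
        )
        if self.normalized is not None:
            sub.normalized = self.normalized[np.ix_(gm, cm)]
        sub.flags = {k: np.asarray(v)[cm] for k, v in self.flags.items()}
        return sub

    def copy(self) -> "CellCohort":
        out = CellCohort(self.counts.copy(), self.gene_ids.copy(), self.cell_meta.copy())
        out.normalized = None if self.normalized is None else self.normalized.copy()
        out.flags = {k: v.copy() for k, v in self.flags.items()}
        return out


# A named collection of gene-symbol sets (markers, states, stemness sets ...).
GeneSetCollection = dict


@dataclass
class SignaturePair:
    """Senescence and stemness signatures with per-gene provenance tags."""

    senescence_genes: set
    stemness_genes: set
    provenance: pd.DataFrame  # columns: gene, signature, source
    overlap: set = field(default_factory=set)


@dataclass
class ClusterState:
    """Per-cell labels plus per-cluster diagnostics from the refine stage."""

    labels: pd.Series  # indexed by cell_id
    purity: pd.Series | None = None  # per cluster, NaN = not computable
    degs: dict | None = None  # cluster -> ranked DataFrame
    profiles: pd.DataFrame | None = None  # genes x clusters mean expression
    resolution_table: pd.DataFrame | None = None


def as_bool_array(x, n: int) -> np.ndarray:
    a = np.asarray(x, dtype=bool)
    if a.shape != (n,):
        raise ValueError(f"expected boolean vector of length {n}, got shape {a.shape}")
    return a


__all__ = [
    "CellCohort",
    "ClusterState",
    "FormatError",
    "GeneSetCollection",
    "InvalidConfigError",
    "SignaturePair",
    "CELL_META_COLUMNS",
    "as_bool_array",
]
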