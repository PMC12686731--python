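"""Sample/cell/gene admission rules, normalization, HVG selection, batch centering.

Admission follows a fixed order: samples with too few cells are dropped
first, then genes expressed in too few cells, then cells with too few
expressed genes or an excessive mitochondrial count fraction (computed on
the pre-filter counts).  Normalization is depth scaling to 10,000 counts
per cell followed by log1p.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import CellCohort

log = logging.getLogger(__name__)


@dataclass
class QCParams:
    min_cells_per_sample: int = 2000
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.20
    n_hvg: int = 2000
    mito_prefix: str = "MT-"

    def validate(self) -> None:
        if min(self.min_cells_per_sample, self.min_cells_per_gene,
               self.min_genes_per_cell, self.n_hvg) < 0:
            raise ValueError("QC thresholds must be nonnegative")
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in (0, 1]")


def admit_samples(cohort: CellCohort, params: QCParams) -> CellCohort:
    """Keep only cells from samples with at least ``min_cells_per_sample`` cells."""
    params.validate()
    sizes = cohort.cell_meta["sample"].value_counts()
    keep_samples = set(sizes[sizes >= params.min_cells_per_sample].index)
    mask = cohort.cell_meta["sample"].isin(keep_samples).to_numpy()
    dropped = sizes[~sizes.index.isin(keep_samples)]
    if len(dropped):
        log.info("admit_samples: dropping %d samples (%d cells): %s",
                 len(dropped), int(dropped.sum()), dict(dropped))
    if not mask.any():
        warnings.warn("admit_samples removed every cell")
    return cohort.subset(cell_mask=mask)


def qc_filter(cohort: CellCohort, params: QCParams) -> CellCohort:
    """Apply the gene filter, then the cell filters, in a single pass.

    Genes expressed (count > 0) in fewer than ``min_cells_per_gene`` cells
    are removed first.  Cells are then removed when they express fewer than
    ``min_genes_per_cell`` of the surviving genes, or when their
    mitochondrial count fraction — computed on the pre-filter counts over
    genes whose symbol starts with ``mito_prefix`` — exceeds
    ``max_mito_fraction``.
    """
    params.validate()
    counts = cohort.counts
    mito_rows = np.array(
        [g.startswith(params.mito_prefix) for g in cohort.gene_ids], dtype=bool
    )
    total = np.asarray(counts.sum(axis=0)).ravel()
    mito = np.asarray(counts[mito_rows].sum(axis=0)).ravel() if mito_rows.any() else np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    cells_per_gene = np.asarray((counts > 0).sum(axis=1)).ravel()
    gene_mask = cells_per_gene >= params.min_cells_per_gene

    genes_per_cell = np.asarray((counts[gene_mask] > 0).sum(axis=0)).ravel()
    cell_mask = (genes_per_cell >= params.min_genes_per_cell) & (
        mito_frac <= params.max_mito_fraction
    )
    log.info("qc_filter: kept %d/%d genes, %d/%d cells",
             int(gene_mask.sum()), cohort.n_genes, int(cell_mask.sum()), cohort.n_cells)
    return cohort.subset(gene_mask=gene_mask, cell_mask=cell_mask)


def normalize_log(cohort: CellCohort, target_sum: float = 1e4) -> CellCohort:
    """Depth-scale each cell to ``target_sum`` counts, then log1p.

    Zero-depth cells are excluded with a warning.  The original counts are
    preserved; the normalized dense matrix is stored on the returned cohort.
    """
    depth = np.asarray(cohort.counts.sum(axis=0)).ravel().astype(float)
    keep = depth > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-depth cells")
        cohort = cohort.subset(cell_mask=keep)
        depth = depth[keep]
    dense = cohort.counts.toarray().astype(float)
    out = cohort.copy()
    out.normalized = np.log1p(dense * (target_sum / depth)[None, :])
    return out


def select_hvg(cohort: CellCohort, n_hvg: int, n_bins: int = 20) -> pd.Index:
    """Rank genes by binned standardized dispersion; return the top ``n_hvg``.

    Dispersion = variance of the log-normalized expression, z-scored within
    ``n_bins`` mean-expression bins.  Ties break by gene symbol so the
    selection is deterministic and invariant to cell order.
    """
    if cohort.normalized is None:
        raise ValueError("call normalize_log first")
    if n_hvg > cohort.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds {cohort.n_genes} genes")
    X = cohort.normalized
    mean = X.mean(axis=1)
    var = X.var(axis=1)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum((np.arange(len(mean)) * n_bins) // len(mean), n_bins - 1)
    z = np.zeros_like(var)
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            continue
        mu, sd = var[m].mean(), var[m].std()
        z[m] = (var[m] - mu) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf  # constant genes rank behind every variable gene
    ranking = pd.DataFrame({"z": z, "gene": cohort.gene_ids}).sort_values(
        ["z", "gene"], ascending=[False, True], kind="stable"
    )
    return pd.Index(ranking["gene"].head(n_hvg))


def center_batches(cohort: CellCohort, batch_labels=None) -> CellCohort:
    """Shift each gene's per-batch mean to its global mean, in log space.

    A linear stand-in for embedding-based batch integration: it removes
    additive per-(batch, gene) offsets exactly and leaves within-batch cell
    ranking per gene unchanged.  Single-cell batches are left unadjusted.
    """
    if cohort.normalized is None:
        raise ValueError("call normalize_log first")
    labels = pd.Series(
        batch_labels if batch_labels is not None else cohort.cell_meta["batch"],
        index=cohort.cell_ids,
    )
    X = cohort.normalized
    out = cohort.copy()
    out.normalized = X.copy()
    global_mean = X.mean(axis=1)
    for b, idx in labels.groupby(labels).groups.items():
        cols = cohort.cell_ids.get_indexer(idx)
        if len(cols) < 2:
            warnings.warn(f"batch {b!r} has a single cell; left unadjusted")
            continue
        shift = global_mean - X[:, cols].mean(axis=1)
        out.normalized[:, cols] += shift[:, None]
    return out


__all__ = ["QCParams", "admit_samples", "center_batches", "normalize_log",
           "qc_filter", "select_hvg"]
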