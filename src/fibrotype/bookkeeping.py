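"""Atlas bookkeeping: the published per-dataset fibroblast counts and the
arithmetic consistency checks derived from them.

The packaged ``dataset_counts.tsv`` holds the per-dataset cell tallies of
the integrated fibroblast atlas (cells called fibroblast by the original
metadata, by the clustering pipeline, passing the NES filter, agreed by
the external classifier, and surviving the full consensus QC).  The
functions below recompute the headline ratios from those integers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# headline totals as published with the atlas
PIPELINE_FIBROBLASTS = 347_688
METADATA_FIBROBLASTS = 256_711
RETAINED_FIBROBLASTS = 157_984
LUNG_FIBROBLASTS = 36_818
PLEURAL_FIBROBLASTS = 14_559
N_SUBTYPES = 16
N_STATES = 16
N_TRAITS = 74


def load_dataset_counts() -> pd.DataFrame:
    """Per-dataset fibroblast tallies shipped with the package."""
    with resources.files("fibrotype.data").joinpath("dataset_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def after_qc_total(counts: pd.DataFrame | None = None) -> int:
    counts = counts if counts is not None else load_dataset_counts()
    return int(counts["fb_after_qc"].sum())


def retention_vs_pipeline_pct(counts: pd.DataFrame | None = None) -> float:
    """Retained consensus fibroblasts as a percent of pipeline-identified ones."""
    return 100.0 * after_qc_total(counts) / PIPELINE_FIBROBLASTS


def retention_vs_metadata_pct(counts: pd.DataFrame | None = None) -> float:
    return 100.0 * after_qc_total(counts) / METADATA_FIBROBLASTS


def tissue_share_pct(n_tissue_cells: int, total: int = RETAINED_FIBROBLASTS) -> float:
    """Share of the retained fibroblast pool held by one tissue, in percent."""
    return 100.0 * n_tissue_cells / total


def n_unordered_pairs(n_states: int = N_STATES) -> int:
    """Number of unordered state pairs tested per subtype."""
    return n_states * (n_states - 1) // 2


def n_trait_subtype_tests(n_traits: int = N_TRAITS, n_subtypes: int = N_SUBTYPES) -> int:
    return n_traits * n_subtypes


__all__ = [
    "LUNG_FIBROBLASTS",
    "METADATA_FIBROBLASTS",
    "N_STATES",
    "N_SUBTYPES",
    "N_TRAITS",
    "PIPELINE_FIBROBLASTS",
    "PLEURAL_FIBROBLASTS",
    "RETAINED_FIBROBLASTS",
    "after_qc_total",
    "load_dataset_counts",
    "n_trait_subtype_tests",
    "n_unordered_pairs",
    "retention_vs_metadata_pct",
    "retention_vs_pipeline_pct",
    "tissue_share_pct",
]
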