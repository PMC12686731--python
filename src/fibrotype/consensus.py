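"""Consensus definition of high-confidence fibroblasts.

A cell is retained when four independent lines of evidence agree: the
clustering pipeline called it a fibroblast, the originating study's
metadata did, its per-cell normalized enrichment score (NES) against a
fibroblast marker set exceeds a threshold, and an external cell-type
classifier agrees.  Canonical markers (COL1A1/COL1A2 by default) are
checked for verification but never used to filter.

The per-cell NES is a weighted Kolmogorov-Smirnov running-sum enrichment
statistic: genes are ranked by normalized expression (descending, ties
broken by symbol); in-set steps are weighted by expression, out-of-set
steps are uniform; the enrichment score ES is the running sum at its
maximal absolute deviation; NES divides ES by the mean positive ES over
seeded gene-label permutations.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from ._types import CellCohort

FIBRO_LABEL = "fibroblast"


@dataclass
class ConsensusParams:
    marker_set: tuple = ()
    nes_threshold: float = 1.0
    n_permutations: int = 200
    canonical_markers: tuple = ("COL1A1", "COL1A2")
    canonical_min_count: int = 1  # strict: count > canonical_min_count
    fibro_label: str = FIBRO_LABEL
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if len(self.marker_set) == 0:
            raise ValueError("marker_set must be nonempty")


@dataclass
class ConsensusReport:
    flags: pd.DataFrame  # per-cell booleans + nes column
    retained_ids: pd.Index
    retention_vs_pipeline: float
    retention_vs_metadata: float
    canonical_fraction: float = float("nan")
    extras: dict = field(default_factory=dict)


def _ranked_es(W: np.ndarray, M: np.ndarray) -> np.ndarray:
    """ES per row for ranked weights W and ranked in-set indicator M.

    W, M: (n_cells, n_genes) already in per-cell rank order (descending).
    """
    n_genes = W.shape[1]
    m = M.sum(axis=1, keepdims=True).astype(float)
    hit_w = W * M
    denom = hit_w.sum(axis=1, keepdims=True)
    # cells expressing no marker fall back to unweighted in-set steps
    flat = denom.ravel() <= 0
    if flat.any():
        hit_w[flat] = M[flat]
        denom[flat] = m[flat]
    hit = np.cumsum(hit_w, axis=1) / denom
    miss = np.cumsum(1.0 - M, axis=1) / np.maximum(n_genes - m, 1.0)
    running = hit - miss
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def cell_nes(
    cohort: CellCohort,
    marker_set,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Per-cell NES of ``marker_set`` in the log-normalized expression.

    Deterministic for a fixed seed; the null uses gene-label permutations
    shared across cells.
    """
    if cohort.normalized is None:
        raise ValueError("call normalize_log first")
    genes = cohort.gene_ids
    in_set = genes.isin(set(marker_set))
    n_overlap = int(in_set.sum())
    if n_overlap == 0:
        raise ValueError("marker set does not overlap the gene universe")
    if n_overlap < 5:
        warnings.warn(f"marker set overlaps only {n_overlap} genes")

    X = cohort.normalized  # genes x cells
    G, C = X.shape
    sym_rank = np.argsort(np.argsort(genes.to_numpy()))  # tie-break by symbol

    # per-cell descending rank order with symbol tie-break
    order = np.empty((C, G), dtype=np.int64)
    for c in range(C):
        order[c] = np.lexsort((sym_rank, -X[:, c]))
    W = np.abs(X.T[np.arange(C)[:, None], order])

    es = _ranked_es(W, in_set[order].astype(float))

    rng = np.random.default_rng(seed)
    null_sum = np.zeros(C)
    null_n = np.zeros(C)
    for _ in range(n_permutations):
        perm_set = np.zeros(G, dtype=float)
        perm_set[rng.choice(G, size=n_overlap, replace=False)] = 1.0
        es_p = _ranked_es(W, perm_set[order])
        pos = es_p > 0
        null_sum[pos] += es_p[pos]
        null_n[pos] += 1
    norm = np.where(null_n > 0, null_sum / np.maximum(null_n, 1), np.nan)
    # cells whose null never went positive: normalize by the global mean
    fallback = np.nanmean(norm) if np.isfinite(norm).any() else 1.0
    norm = np.where(np.isfinite(norm) & (norm > 0), norm, fallback)
    return pd.Series(es / norm, index=cohort.cell_ids, name="nes")


def _to_flag(labels, cell_ids: pd.Index, fibro_label: str) -> np.ndarray:
    if labels is None:
        raise ValueError("missing label vector for consensus filtering")
    ser = pd.Series(labels)
    if ser.dtype == bool:
        if len(ser) != len(cell_ids):
            raise ValueError("boolean flag length mismatch")
        return ser.to_numpy()
    ser.index = pd.Index(ser.index)
    if not cell_ids.isin(ser.index).all():
        if len(ser) == len(cell_ids):
            ser.index = cell_ids
        else:
            missing = cell_ids.difference(ser.index)
            raise ValueError(f"labels missing cells: {list(missing[:10])}")
    return (ser.reindex(cell_ids).astype(str) == fibro_label).to_numpy()


def canonical_marker_fraction(cohort: CellCohort, canonical_markers, min_count: int = 1) -> float:
    """Fraction of cells with raw count strictly above ``min_count`` in any marker."""
    rows = cohort.gene_ids.get_indexer(list(canonical_markers))
    absent = [m for m, r in zip(canonical_markers, rows) if r < 0]
    if absent:
        warnings.warn(f"canonical markers absent (treated as all-zero): {absent}")
    rows = rows[rows >= 0]
    if len(rows) == 0:
        return 0.0
    sub = cohort.counts[rows].toarray()
    return float((sub > min_count).any(axis=0).mean())


def consensus_filter(
    cohort: CellCohort,
    pipeline_labels,
    metadata_labels,
    classifier_labels,
    params: ConsensusParams,
    nes: pd.Series | None = None,
):
    """Intersect the four evidence flags; return report + filtered cohort.

    ``canonical_pass`` is computed and reported but does not gate retention.
    """
    params.validate()
    ids = cohort.cell_ids
    pipeline = _to_flag(pipeline_labels, ids, params.fibro_label)
    metadata = _to_flag(metadata_labels, ids, params.fibro_label)
    classifier = _to_flag(classifier_labels, ids, params.fibro_label)
    if nes is None:
        nes = cell_nes(cohort, params.marker_set, params.n_permutations, params.seed)
    nes = nes.reindex(ids)
    nes_pass = (nes > params.nes_threshold).to_numpy()

    rows = cohort.gene_ids.get_indexer(list(params.canonical_markers))
    canon = np.zeros(len(ids), dtype=bool)
    valid = rows[rows >= 0]
    if len(valid):
        canon = (cohort.counts[valid].toarray() > params.canonical_min_count).any(axis=0)

    retained = pipeline & metadata & nes_pass & classifier
    flags = pd.DataFrame(
        {
            "pipeline_fibro": pipeline,
            "metadata_fibro": metadata,
            "nes": nes.to_numpy(),
            "nes_pass": nes_pass,
            "classifier_pass": classifier,
            "canonical_pass": canon,
            "retained": retained,
        },
        index=ids,
    )
    report = ConsensusReport(
        flags=flags,
        retained_ids=ids[retained],
        retention_vs_pipeline=float(retained.sum() / pipeline.sum()) if pipeline.any() else float("nan"),
        retention_vs_metadata=float(retained.sum() / metadata.sum()) if metadata.any() else float("nan"),
        canonical_fraction=float(canon[retained].mean()) if retained.any() else float("nan"),
    )
    return report, cohort.subset(cell_mask=retained)


def classifier_adapter(cohort: CellCohort, backend: str) -> pd.Series:
    """Obtain per-cell type labels from a pluggable classifier backend.

    ``mock:<tsv>`` reads a (cell_id, label) table; any other string is run
    as a shell command expected to emit the same table on stdout.  Output
    is realigned to the cohort's cells; a backend omitting any cell raises
    an error naming it; null labels become ``"unassigned"``.
    """
    if backend.startswith("mock:"):
        raw = pd.read_csv(backend[len("mock:"):], sep="\t", comment="#")
    else:
        proc = subprocess.run(backend, shell=True, check=True, capture_output=True, text=True)
        raw = pd.read_csv(StringIO(proc.stdout), sep="\t", comment="#")
    ser = raw.set_index(raw.columns[0])[raw.columns[1]]
    missing = cohort.cell_ids.difference(ser.index)
    if len(missing):
        raise ValueError(f"classifier backend omitted cells: {list(missing[:10])}")
    out = ser.reindex(cohort.cell_ids)
    return out.fillna("unassigned").astype(str)


__all__ = [
    "ConsensusParams",
    "ConsensusReport",
    "canonical_marker_fraction",
    "cell_nes",
    "classifier_adapter",
    "consensus_filter",
]
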