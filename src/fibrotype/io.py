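"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket (genes x cells) with sibling ``genes.tsv`` and
``cells.tsv`` tables; gene sets as GMT; everything else as TSV.  Output
tables carry a provenance comment line ``# fibrotype <stage> <version>``.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._types import CELL_META_COLUMNS, CellCohort, FormatError

PKG_VERSION = "0.1.0"


def _provenance_line(stage: str, params: dict | None = None) -> str:
    h = ""
    if params:
        digest = hashlib.sha1(repr(sorted(params.items())).encode()).hexdigest()[:8]
        h = f" {digest}"
    return f"# fibrotype {stage} {PKG_VERSION}{h}\n"


def write_table(df: pd.DataFrame, path, stage: str, params: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(stage, params))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gmt(gene_sets: dict, path, description: str = "fibrotype") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_gmt(path) -> dict:
    """Read a GMT file into an ordered ``{name: [genes]}`` dict."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_cohort(cohort: CellCohort, outdir) -> None:
    """Write counts.mtx + genes.tsv + cells.tsv for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), cohort.counts.astype(np.int64))
    pd.DataFrame({"gene_id": cohort.gene_ids}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    cells = cohort.cell_meta.reset_index(names="cell_id")
    cells[["cell_id", *CELL_META_COLUMNS]].to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )


def read_cohort(mtx_path, genes_path, cells_path) -> CellCohort:
    """Read a cohort from MatrixMarket counts plus gene/cell tables.

    Duplicate gene symbols are collapsed by summation (with a warning);
    dimension mismatches and non-integer entries raise :class:`FormatError`.
    """
    for p in (mtx_path, genes_path, cells_path):
        if not Path(p).exists():
            raise FormatError(f"missing input file: {p}")
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    if mat.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("count matrix contains non-integer entries")
    mat = mat.astype(np.int64)

    genes = pd.read_csv(genes_path, sep="\t")
    gene_col = "gene_id" if "gene_id" in genes.columns else genes.columns[0]
    symbols = genes[gene_col].astype(str)
    if len(symbols) != mat.shape[0]:
        raise FormatError(
            f"genes table has {len(symbols)} rows for a {mat.shape[0]}-row matrix"
        )

    cells = pd.read_csv(cells_path, sep="\t")
    if "cell_id" not in cells.columns:
        raise FormatError("cells table must have a cell_id column")
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"cells table has {len(cells)} rows for a {mat.shape[1]}-column matrix"
        )
    cells = cells.set_index("cell_id")

    if symbols.duplicated().any():
        dup = sorted(symbols[symbols.duplicated()].unique())
        warnings.warn(f"collapsing duplicated gene symbols by summation: {dup}")
        codes, uniques = pd.factorize(symbols)
        collapse = sp.csr_matrix(
            (np.ones(len(codes)), (codes, np.arange(len(codes)))),
            shape=(len(uniques), len(codes)),
        )
        mat = (collapse @ mat).tocsr().astype(np.int64)
        symbols = pd.Series(uniques)

    return CellCohort(counts=mat, gene_ids=pd.Index(symbols), cell_meta=cells)


def read_cohort_dir(indir) -> CellCohort:
    indir = Path(indir)
    return read_cohort(indir / "counts.mtx", indir / "genes.tsv", indir / "cells.tsv")


def read_labels(path, cell_ids: pd.Index | None = None) -> pd.Series:
    """Read a (cell_id, label) TSV, optionally realigned to ``cell_ids``.

    Cells absent from the file raise an error naming the missing ids.
    """
    df = read_table(path)
    if df.shape[1] < 2:
        raise FormatError("labels file needs cell_id and label columns")
    ser = df.set_index(df.columns[0])[df.columns[1]]
    if cell_ids is not None:
        missing = cell_ids.difference(ser.index)
        if len(missing):
            raise FormatError(f"labels file missing cells: {list(missing[:10])}")
        ser = ser.reindex(cell_ids)
    return ser


__all__ = [
    "read_cohort",
    "read_cohort_dir",
    "read_gmt",
    "read_labels",
    "read_table",
    "write_cohort",
    "write_gmt",
    "write_table",
]
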