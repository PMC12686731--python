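"""Admission rules, normalization and HVG selection on the simulated cohort.

Reads scratch/sim/single_cell, applies the sample/gene/cell filters,
normalizes, optionally centers batches, and writes the processed cohort
plus the HVG list to scratch/qc/; a QC summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from fibrotype import io, qc

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "sim" / "single_cell"
OUT = ROOT / "scratch" / "qc"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = io.read_cohort_dir(IN)
    params = qc.QCParams(min_cells_per_sample=100)  # synthetic samples are small
    before = (cohort.n_genes, cohort.n_cells)
    cohort = qc.admit_samples(cohort, params)
    cohort = qc.qc_filter(cohort, params)
    cohort = qc.normalize_log(cohort)
    cohort = qc.center_batches(cohort)
    hvg = qc.select_hvg(cohort, min(1000, cohort.n_genes))

    io.write_cohort(cohort, OUT)
    io.write_table(pd.DataFrame({"gene": hvg}), OUT / "hvg.tsv", "qc")
    summary = pd.DataFrame([{
        "genes_before": before[0], "cells_before": before[1],
        "genes_after": cohort.n_genes, "cells_after": cohort.n_cells,
        "n_hvg": len(hvg),
    }])
    io.write_table(summary, RESULTS / "qc_summary.tsv", "qc")
    print(f"QC: {before[0]}x{before[1]} -> {cohort.n_genes}x{cohort.n_cells}; "
          f"{len(hvg)} HVGs")


if __name__ == "__main__":
    main()
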