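"""Signature enrichment and survival stratification in the bulk cohort.

Scores each planted subtype's markers in the bulk samples with the
rank-weighted single-sample statistic, splits samples at the per-set mean
score, and compares the groups by log-rank and a covariate-adjusted Cox
model.  Only the planted hazard-bearing signature should associate.
"""

from pathlib import Path

import pandas as pd

from fibrotype import io
from fibrotype.assoc import (
    log10_transform,
    signature_matrix,
    ssgsea_scores,
    survival_screen,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
QC = ROOT / "scratch" / "qc"
RESULTS = ROOT / "results"


def main() -> None:
    expr = pd.read_csv(SIM / "bulk" / "expression.tsv", sep="\t", index_col=0)
    surv = pd.read_csv(SIM / "bulk" / "survival.tsv", sep="\t", index_col=0)
    markers = io.read_gmt(SIM / "single_cell" / "truth_markers.gmt")

    enr = ssgsea_scores(log10_transform(expr), markers)
    io.write_table(enr.round(4).reset_index(names="sample_id"),
                   RESULTS / "enrichment_matrix.tsv", "assoc")
    results = survival_screen(enr, surv, covariate_cols=("age", "stage"))
    io.write_table(results.round(5), RESULTS / "survival_results.tsv", "assoc")

    # reference profile matrix from the single-cell side
    from fibrotype import qc as qc_mod

    cohort = qc_mod.normalize_log(io.read_cohort_dir(QC))
    truth = io.read_labels(SIM / "single_cell" / "truth_subtypes.tsv",
                           cohort.cell_ids)
    profiles = signature_matrix(cohort, truth.to_numpy())
    io.write_table(profiles.round(4).reset_index(names="gene"),
                   RESULTS / "signature_matrix.tsv", "assoc")

    tab = results.set_index("set")
    hit = tab.loc["subtype_0"]
    others = tab.drop("subtype_0")
    # rank-based single-sample scores are compositional: when the planted
    # signature rises with the hazard-bearing activity, other signatures'
    # ranks fall, so they can show mirrored (protective) associations
    print(f"survival screen over {len(results)} signatures; planted signature: "
          f"log-rank p={hit['logrank_p']:.2e}, HR={hit['logrank_hr']:.2f}, "
          f"Cox HR={hit['cox_hr']:.2f} (p={hit['cox_p']:.2e}); other signatures "
          f"(compositional mirror, HR<1): "
          f"{int(((others['logrank_p'] < 0.05) & (others['logrank_hr'] < 1)).sum())}"
          f" of {len(others)} significant")


if __name__ == "__main__":
    main()
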