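"""Age-trend regression and senescence/stemness signature construction.

Module scores of the planted trend sets (plus null sets) are regressed on
the ordinal age encoding; sets passing |t| > 30 split into differentiation
and stemness sets, whose unions combine with curated over-/under-expressed
senescence genes into the two signatures; cells are scored and age-group
enrichment is tested.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fibrotype import io, qc
from fibrotype.age import (
    age_group_enrichment,
    build_signatures,
    compare_scores_by_age,
    fit_age_trend,
    partition_sets,
    score_pluripotency,
)
from fibrotype.scoring import ModuleScoreParams, score_gene_sets

ROOT = Path(__file__).resolve().parents[1]
QC = ROOT / "scratch" / "qc"
SIM = ROOT / "scratch" / "sim" / "single_cell"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    cohort = qc.normalize_log(io.read_cohort_dir(QC))
    truth = io.read_labels(SIM / "truth_subtypes.tsv", cohort.cell_ids)
    trend_sets = io.read_gmt(SIM / "truth_trend_sets.gmt")
    rng = np.random.default_rng(SEED + 1)
    planted = {g for genes in trend_sets.values() for g in genes}
    pool = [g for g in cohort.gene_ids if g not in planted]
    null_sets = {f"null_{i}": list(rng.choice(pool, 50, replace=False))
                 for i in range(10)}
    sets = {**trend_sets, **null_sets}

    scores = score_gene_sets(cohort, sets, ModuleScoreParams(seed=SEED))
    trend = fit_age_trend(scores, cohort.cell_meta["age_group"])
    io.write_table(trend.round(4), RESULTS / "age_trend.tsv", "age")

    diff, stem, diff_union, stem_union = partition_sets(trend, sets, 30.0)
    # curated senescence genes stand in for an external resource: a seeded
    # draw outside the planted sets
    over = list(rng.choice(pool, 60, replace=False))
    under = list(rng.choice(pool, 40, replace=False))
    pair = build_signatures(diff_union, stem_union, over, under)
    io.write_gmt({"senescence": sorted(pair.senescence_genes),
                  "stemness": sorted(pair.stemness_genes)},
                 RESULTS / "signatures.gmt")

    pluri = score_pluripotency(cohort, diff_union, stem_union, over, under,
                               ModuleScoreParams(seed=SEED))
    io.write_table(pluri.round(4).reset_index(names="cell_id"),
                   RESULTS / "pluripotency_scores.tsv", "age")

    ages = cohort.cell_meta["age_group"].to_numpy()
    enrich = age_group_enrichment(truth.to_numpy(), ages)
    io.write_table(enrich, RESULTS / "age_enrichment.tsv", "age")
    ttests = compare_scores_by_age(pluri["senescence_signature"].to_numpy(),
                                   truth.to_numpy(), ages)
    io.write_table(ttests, RESULTS / "age_score_tests.tsv", "age")

    by_age = pluri.groupby(ages)["senescence_signature"].mean()
    print(f"trend partition: {len(diff)} differentiation / {len(stem)} stemness sets; "
          f"signatures: senescence={len(pair.senescence_genes)} genes, "
          f"stemness={len(pair.stemness_genes)} genes "
          f"(overlap {len(pair.overlap)}); senescence score by age: "
          f"{by_age.round(3).to_dict()}")


if __name__ == "__main__":
    main()
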