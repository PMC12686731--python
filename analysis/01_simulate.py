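"""Generate the synthetic study cohorts every later stage consumes.

Writes a planted 5-subtype single-cell cohort (MatrixMarket + TSV + truth
files), a bulk expression/survival cohort whose hazard tracks a planted
signature, and GWAS-style trait gene lists, under scratch/sim/.
"""

from pathlib import Path

import pandas as pd

from fibrotype import io
from fibrotype.simulate import (
    BulkSimConfig,
    SimConfig,
    generate_bulk_survival,
    generate_cohort,
    generate_trait_lists,
)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"
SEED = 1


def main() -> None:
    sc_dir = OUT / "single_cell"
    cfg = SimConfig(n_genes=2000, n_cells=5000, n_subtypes=5,
                    markers_per_subtype=60, marker_log2fc=2.0,
                    n_trend_sets=4, trend_genes_per_set=50,
                    trend_slope=0.35, seed=SEED)
    syn = generate_cohort(cfg)
    io.write_cohort(syn.cohort, sc_dir)
    io.write_table(syn.truth_subtype.rename("subtype").rename_axis("cell_id").reset_index(),
                   sc_dir / "truth_subtypes.tsv", "simulate")
    io.write_gmt(syn.truth_markers, sc_dir / "truth_markers.gmt")
    io.write_gmt(syn.truth_trend_sets, sc_dir / "truth_trend_sets.gmt")
    print(f"single-cell cohort: {syn.cohort.n_genes} genes x "
          f"{syn.cohort.n_cells} cells, 5 planted subtypes -> {sc_dir}")

    bulk_dir = OUT / "bulk"
    bulk_dir.mkdir(parents=True, exist_ok=True)
    sig = syn.truth_markers["subtype_0"]
    bcfg = BulkSimConfig(n_samples=400, signature=tuple(sig),
                         gene_universe=tuple(syn.cohort.gene_ids),
                         enrichment_effect=1.2, hazard_ratio_per_sd=2.0,
                         covariates=(("age", 0.3), ("stage", 0.2)), seed=SEED)
    expr, surv = generate_bulk_survival(bcfg)
    expr.to_csv(bulk_dir / "expression.tsv", sep="\t")
    surv.to_csv(bulk_dir / "survival.tsv", sep="\t")
    print(f"bulk cohort: {expr.shape[0]} genes x {expr.shape[1]} samples, "
          f"planted HR=2 per sd of signature activity -> {bulk_dir}")

    trait_dir = OUT / "traits"
    trait_dir.mkdir(parents=True, exist_ok=True)
    traits = generate_trait_lists(74, syn.truth_markers, overlap_frac=0.0,
                                  seed=SEED, list_size=200,
                                  universe=list(syn.cohort.gene_ids))
    # plant real signal in a handful of traits against subtype_1 markers
    planted = generate_trait_lists(6, syn.truth_markers, overlap_frac=0.15,
                                   seed=SEED + 1, list_size=200,
                                   universe=list(syn.cohort.gene_ids),
                                   target_set="subtype_1")
    for i, (name, df) in enumerate(planted.items()):
        traits[f"trait_{68 + i:03d}"] = df
    for name, df in traits.items():
        df.to_csv(trait_dir / f"{name}.tsv", sep="\t", index=False)
    print(f"{len(traits)} trait gene lists (6 with planted subtype_1 overlap) "
          f"-> {trait_dir}")


if __name__ == "__main__":
    main()
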