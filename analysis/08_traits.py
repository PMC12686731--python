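"""Trait-to-subtype association and two-method concordance.

Tests every trait gene list against every subtype's DEGs by one-sided
Fisher's exact test, builds a second (module-score-based, scDRS-style)
per-cell association route, and quantifies the concordance of the two
significant sets with a 2x2 Fisher test.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fibrotype import io, qc
from fibrotype.assoc import method_concordance, trait_overlap
from fibrotype.scoring import ModuleScoreParams, score_gene_sets

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
QC = ROOT / "scratch" / "qc"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    trait_dir = SIM / "traits"
    traits = {p.stem: pd.read_csv(p, sep="\t") for p in sorted(trait_dir.glob("*.tsv"))}
    degs = pd.read_csv(RESULTS / "degs.tsv", sep="\t", comment="#")
    deg_sets = {str(c): list(g["gene"]) for c, g in degs.groupby("cluster")}

    cohort = qc.normalize_log(io.read_cohort_dir(QC))
    overlap = trait_overlap(traits, deg_sets, universe_size=cohort.n_genes)
    io.write_table(overlap.round(6), RESULTS / "trait_associations.tsv", "assoc")
    sig_fisher = {(r.trait, r.subtype) for r in overlap.itertuples()
                  if r.p < 0.05}

    # second route: per-cell trait module scores, association when a
    # subtype's mean score is in the top tail of a label permutation null;
    # uses the same refined labels as the Fisher route
    truth = io.read_labels(RESULTS / "labels_final.tsv",
                           cohort.cell_ids).astype(str).to_numpy()
    scores = score_gene_sets(
        cohort, {t: list(df["gene"]) for t, df in traits.items()},
        ModuleScoreParams(seed=SEED),
    )
    rng = np.random.default_rng(SEED)
    sig_cell = set()
    rows = []
    for trait in scores.columns:
        obs = scores[trait].groupby(truth).mean()
        null = np.empty((200, len(obs)))
        for b in range(200):
            null[b] = scores[trait].groupby(rng.permutation(truth)).mean()
        for j, subtype in enumerate(obs.index):
            p = (1 + (null[:, j] >= obs.iloc[j]).sum()) / 201
            rows.append({"trait": trait, "subtype": subtype,
                         "mean_score": obs.iloc[j], "p": p})
            if p < 0.05:
                sig_cell.add((trait, subtype))
    io.write_table(pd.DataFrame(rows).round(6),
                   RESULTS / "trait_cell_scores.tsv", "assoc")

    n_total = len(traits) * len(deg_sets)
    conc = method_concordance(sig_fisher, sig_cell, n_total)
    io.write_table(pd.DataFrame([{
        "n_fisher": len(sig_fisher), "n_cell": len(sig_cell),
        "n_concordant": conc["n_concordant"], "n_total": n_total,
        "odds_ratio": conc["odds_ratio"], "p": conc["p"],
    }]), RESULTS / "concordance.tsv", "assoc")
    print(f"{n_total} trait-subtype tests: {len(sig_fisher)} significant by "
          f"Fisher overlap, {len(sig_cell)} by per-cell scoring, "
          f"{conc['n_concordant']} concordant (Fisher p={conc['p']:.2e})")


if __name__ == "__main__":
    main()
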