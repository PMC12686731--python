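# fibrotype

Fibroblasts are the stromal cells that build and maintain the extracellular
matrix; in disease and cancer they adopt activated states (CAFs — including
myofibroblastic, inflammatory, and antigen-presenting subtypes) that shape
outcomes. Large single-cell atlases identify fibroblast subtypes by
clustering, but the decisions involved — which cells are confidently
fibroblasts, which clustering resolution to trust, when two clusters are
really one subtype — are usually ad hoc. `fibrotype` implements that whole
decision chain as a tested, seeded pipeline, exercised end-to-end on
synthetic cohorts with known ground truth:

1. **Synthetic cohorts** (`fibrotype.simulate`) — negative-binomial counts
   with variance μ + μ²/θ, planted subtype marker blocks
   (2^`marker_log2fc` boosts), multiplicative per-(batch, gene) effects,
   age-trending gene programs (exp(β·age) with ordinal age 0/1/2), and
   bulk cohorts whose exponential event-time hazard scales as
   HR^z for a latent standard-normal signature activity z.
2. **QC and ingestion** (`fibrotype.qc`) — sample admission (≥ 2000
   cells/sample), gene (≥ 3 cells) then cell (≥ 200 genes, mitochondrial
   fraction ≤ 0.20) filtering, CP10K + log1p normalization, binned-
   dispersion HVG selection, optional per-batch mean centering.
3. **Consensus fibroblast calling** (`fibrotype.consensus`) — a cell is
   retained when four lines of evidence agree: pipeline label, original
   metadata label, external-classifier label, and a per-cell NES > 1
   against a fibroblast marker set. The NES is a weighted
   Kolmogorov–Smirnov running sum over the cell's expression ranking,
   normalized by the mean positive enrichment over seeded gene-label
   permutations. Canonical markers (COL1A1/COL1A2, count > 1) verify but
   never filter.
4. **Subtype refinement** (`fibrotype.refine`) — Louvain-style community
   detection on a kNN graph over a 0–3 resolution grid; the resolution
   with the highest median cluster purity wins. Purity is an entropy
   statistic in [0, 1]: per gene, the expression entropy across the
   cluster's cells is compared with a LOESS baseline in log mean
   expression; the summed significant entropy deficit D gives
   purity = 1 − D/(D + K). Clusters then merge in two stages: shared
   top-20 DEGs (≥ 5 shared, transitive closure, iterated) and greedy
   purity-gain merging. Batch mixing is reported as the local inverse
   Simpson index (LISI).
5. **State scoring** (`fibrotype.scoring`) — Seurat-style binned-control
   module scores (mean of set genes minus expression-matched controls),
   paired t-tests for normal-like vs CAF-like grouping, per-subtype state
   correlations, chi-square composition tests.
6. **Age signatures** (`fibrotype.age`) — gene-set module scores regressed
   on ordinal age; sets with |t| > 30 partition into differentiation and
   stemness programs whose unions combine with curated over-/under-
   expressed senescence genes into senescence and stemness signatures.
7. **Bulk association** (`fibrotype.assoc`) — rank-weighted single-sample
   enrichment of subtype signatures in bulk expression, mean-split
   high/low stratification, a from-scratch log-rank test (O/E hazard
   ratio), covariate-adjusted Cox models, one-sided Fisher trait-gene
   overlap, and a 2×2 concordance test between association methods.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (later steps read the outputs of earlier ones):

```bash
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/04_refine.py
python analysis/07_bulk_survival.py
```

prints, among other lines:

```
single-cell cohort: 2000 genes x 5000 cells, 5 planted subtypes -> scratch/sim/single_cell
QC: 2000x5000 -> 2000x5000; 1000 HVGs
final clusters: 5 (ARI vs planted truth = 1.000); ...
survival screen over 5 signatures; planted signature: log-rank p=5.88e-14,
HR=2.21, Cox HR=2.46 (p=5.52e-14); ...
```

The refinement stage recovers exactly the five planted subtypes (adjusted
Rand index 1.0 against the generator's truth labels), and the bulk screen
flags the hazard-bearing signature with a hazard ratio near the planted
value of 2 — the other signatures show only the mirrored compositional
effect inherent to rank-based scoring. Tables land in `results/`
(resolution scan, purity, DEGs, survival screen, trait associations).

The same stages are scriptable via the `fibrotype` CLI
(`fibrotype simulate|qc|consensus|refine|score|age|assoc --help`).

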