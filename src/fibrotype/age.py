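"""Senescence/stemness signature construction and age-group analyses.

Gene-set module scores are regressed on an ordinal age encoding
(fetal=0, adult=1, elderly=2).  Sets whose slope t-statistic clears a
threshold split into differentiation (t > +T) and stemness (t < -T) sets;
their gene unions combine with externally curated over-/under-expressed
senescence genes into a senescence and a stemness signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from ._types import SignaturePair
from .scoring import ModuleScoreParams, score_gene_sets

DEFAULT_AGE_ENCODING = {"fetal": 0, "adult": 1, "elderly": 2}
T_INFINITY = float("inf")
MIN_CELLS_PER_CONDITION = 100


@dataclass
class AgeSignatureParams:
    age_encoding: dict = field(default_factory=lambda: dict(DEFAULT_AGE_ENCODING))
    t_threshold: float = 30.0
    alpha: float = 0.05

    def validate(self) -> None:
        vals = list(self.age_encoding.values())
        if vals != sorted(vals) or len(set(vals)) != len(vals):
            raise ValueError("age encoding must be strictly increasing")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")


def fit_age_trend(
    module_scores: pd.DataFrame,
    age_groups,
    params: AgeSignatureParams | None = None,
) -> pd.DataFrame:
    """OLS of each set's per-cell module score on the encoded age.

    Returns (set, beta, t, p); an exact zero-residual fit reports
    t = +/-inf, a zero-variance score reports t as missing.
    """
    params = params or AgeSignatureParams()
    params.validate()
    codes = pd.Series(age_groups).map(params.age_encoding)
    if codes.isna().any():
        raise ValueError("unknown age group label")
    x = codes.to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct age groups")
    for v in np.unique(x):
        if (x == v).sum() < 3:
            raise ValueError("each age group needs at least 3 cells")
    rows = []
    for name in module_scores.columns:
        y = module_scores[name].to_numpy(float)
        if np.std(y) == 0:
            rows.append({"set": name, "beta": 0.0, "t": np.nan, "p": np.nan})
            continue
        res = st.linregress(x, y)
        if res.stderr == 0:
            t = np.sign(res.slope) * T_INFINITY if res.slope != 0 else 0.0
            p = 0.0 if res.slope != 0 else 1.0
        else:
            t = res.slope / res.stderr
            p = res.pvalue
        rows.append({"set": name, "beta": res.slope, "t": t, "p": p})
    return pd.DataFrame(rows)


def partition_sets(
    trend_table: pd.DataFrame,
    gene_sets: dict,
    t_threshold: float = 30.0,
):
    """Split sets by trend sign at |t| > threshold; return named sets + unions.

    Returns ``(differentiation_sets, stemness_sets, diff_union, stem_union)``.
    Sets with |t| <= threshold (or missing t) are dropped.
    """
    diff_names = list(trend_table.loc[trend_table["t"] > t_threshold, "set"])
    stem_names = list(trend_table.loc[trend_table["t"] < -t_threshold, "set"])
    if not diff_names and not stem_names:
        warnings.warn("no gene set passed the t-statistic threshold")
    diff_sets = {n: list(gene_sets[n]) for n in diff_names}
    stem_sets = {n: list(gene_sets[n]) for n in stem_names}
    diff_union = sorted({g for gs in diff_sets.values() for g in gs})
    stem_union = sorted({g for gs in stem_sets.values() for g in gs})
    return diff_sets, stem_sets, diff_union, stem_union


def build_signatures(
    diff_union,
    stem_union,
    over_expressed,
    under_expressed,
) -> SignaturePair:
    """Union age-trending genes with curated senescence genes.

    senescence = differentiation-union ∪ over-expressed;
    stemness = stemness-union ∪ under-expressed.  Overlap between the two
    signatures is reported, not removed; provenance records each gene's
    sources.
    """
    senescence = set(diff_union) | set(over_expressed)
    stemness = set(stem_union) | set(under_expressed)
    prov_rows = []
    for sig_name, union_part, curated_part, genes in (
        ("senescence", set(diff_union), set(over_expressed), senescence),
        ("stemness", set(stem_union), set(under_expressed), stemness),
    ):
        curated_tag = "over-expressed" if sig_name == "senescence" else "under-expressed"
        union_tag = "trend-up" if sig_name == "senescence" else "trend-down"
        for g in sorted(genes):
            sources = [tag for tag, part in ((union_tag, union_part), (curated_tag, curated_part)) if g in part]
            prov_rows.append({"gene": g, "signature": sig_name, "source": "+".join(sources)})
    return SignaturePair(
        senescence_genes=senescence,
        stemness_genes=stemness,
        provenance=pd.DataFrame(prov_rows),
        overlap=senescence & stemness,
    )


def score_pluripotency(
    cohort_or_matrix,
    diff_union,
    stem_union,
    over_expressed,
    under_expressed,
    params: ModuleScoreParams | None = None,
    gene_ids=None,
    cell_ids=None,
) -> pd.DataFrame:
    """Four module scores per cell plus the combined signature scores."""
    pair = build_signatures(diff_union, stem_union, over_expressed, under_expressed)
    sets = {
        "differentiation": list(diff_union),
        "stemness": list(stem_union),
        "over_expressed": list(over_expressed),
        "under_expressed": list(under_expressed),
        "senescence_signature": sorted(pair.senescence_genes),
        "stemness_signature": sorted(pair.stemness_genes),
    }
    sets = {k: v for k, v in sets.items() if v}
    return score_gene_sets(cohort_or_matrix, sets, params, gene_ids=gene_ids, cell_ids=cell_ids)


def age_group_enrichment(
    labels,
    age_groups,
    tissues=None,
    alternative: str = "greater",
    alpha_stars=(0.05, 0.01, 0.001),
    min_cells: int = MIN_CELLS_PER_CONDITION,
) -> pd.DataFrame:
    """Fisher's exact test of subtype over-representation per age group.

    Within each tissue (one stratum when ``tissues`` is None), every
    (subtype, age-group) 2x2 table is tested one-sided for enrichment;
    age groups with fewer than ``min_cells`` cells in the stratum are
    skipped; BH-adjusted with star categories.
    """
    labels = np.asarray(labels)
    ages = np.asarray(age_groups)
    tiss = np.asarray(tissues) if tissues is not None else np.repeat("all", len(labels))
    rows = []
    for t in sorted(pd.unique(tiss), key=str):
        tm = tiss == t
        for g in sorted(pd.unique(ages[tm]), key=str):
            if (tm & (ages == g)).sum() < min_cells:
                continue
            for cl in sorted(pd.unique(labels[tm]), key=str):
                a = int((tm & (labels == cl) & (ages == g)).sum())
                b = int((tm & (labels == cl) & (ages != g)).sum())
                c = int((tm & (labels != cl) & (ages == g)).sum())
                d = int((tm & (labels != cl) & (ages != g)).sum())
                odds, p = st.fisher_exact([[a, b], [c, d]], alternative=alternative)
                rows.append({"tissue": t, "subtype": cl, "age_group": g,
                             "n": a, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
        out["stars"] = [_stars(p, alpha_stars) for p in out["adj_p"]]
    return out


def compare_scores_by_age(
    scores,
    labels,
    age_groups,
    tissues=None,
    alpha_stars=(0.05, 0.01, 0.001, 0.0001),
    min_cells: int = MIN_CELLS_PER_CONDITION,
) -> pd.DataFrame:
    """Welch two-sided t test of a score between age groups, per subtype/tissue.

    Only (subtype, tissue, age-pair) strata where both groups hold at least
    ``min_cells`` cells are tested; BH-adjusted across all emitted tests.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    ages = np.asarray(age_groups)
    tiss = np.asarray(tissues) if tissues is not None else np.repeat("all", len(labels))
    rows = []
    for t in sorted(pd.unique(tiss), key=str):
        for cl in sorted(pd.unique(labels), key=str):
            base = (tiss == t) & (labels == cl)
            present = sorted(pd.unique(ages[base]), key=str)
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    m1 = base & (ages == present[i])
                    m2 = base & (ages == present[j])
                    if m1.sum() < min_cells or m2.sum() < min_cells:
                        continue
                    tstat, p = st.ttest_ind(scores[m1], scores[m2], equal_var=False)
                    rows.append({
                        "tissue": t, "subtype": cl,
                        "group_a": present[i], "group_b": present[j],
                        "mean_a": scores[m1].mean(), "mean_b": scores[m2].mean(),
                        "t": tstat, "p": p,
                    })
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
        out["stars"] = [_stars(p, alpha_stars) for p in out["adj_p"]]
    return out


def _stars(p: float, thresholds) -> str:
    return "*" * sum(p < t for t in thresholds)


__all__ = [
    "AgeSignatureParams",
    "age_group_enrichment",
    "build_signatures",
    "compare_scores_by_age",
    "fit_age_trend",
    "partition_sets",
    "score_pluripotency",
]
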