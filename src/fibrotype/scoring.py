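"""Binned-control gene-module scoring and cell-state analyses.

A module score for a gene set is the mean normalized expression of the set
minus the mean of expression-matched control genes: genes are binned by
average expression, and each set gene contributes control genes sampled
(with replacement) from its own bin, excluding the set itself.  Scores are
seeded and bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from ._types import CellCohort


@dataclass
class ModuleScoreParams:
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl_per_gene < 1:
            raise ValueError("n_ctrl_per_gene must be >= 1")


def _matrix_and_genes(cohort_or_matrix, gene_ids):
    if isinstance(cohort_or_matrix, CellCohort):
        if cohort_or_matrix.normalized is None:
            raise ValueError("call normalize_log first")
        return cohort_or_matrix.normalized, cohort_or_matrix.gene_ids
    if gene_ids is None:
        raise ValueError("gene_ids required with a bare matrix")
    return cohort_or_matrix, pd.Index(gene_ids)


def module_score(
    cohort_or_matrix,
    gene_set,
    params: ModuleScoreParams | None = None,
    gene_ids=None,
) -> np.ndarray:
    """Per-cell module score of ``gene_set`` against binned control genes."""
    params = params or ModuleScoreParams()
    params.validate()
    X, genes = _matrix_and_genes(cohort_or_matrix, gene_ids)
    in_set = np.asarray(genes.isin(set(gene_set)))
    if not in_set.any():
        raise ValueError("gene set does not overlap the gene universe")
    if in_set.sum() < 2:
        warnings.warn("gene set overlaps fewer than 2 genes")

    mean_expr = X.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(genes), dtype=int)
    n_bins = min(params.n_bins, len(genes))
    bins[order] = np.minimum((np.arange(len(genes)) * n_bins) // len(genes), n_bins - 1)

    rng = np.random.default_rng(params.seed)
    set_rows = np.flatnonzero(in_set)
    ctrl_sum = np.zeros(X.shape[1])
    n_ctrl_total = 0
    for g in set_rows:
        pool = np.flatnonzero((bins == bins[g]) & ~in_set)
        if len(pool) == 0:
            pool = np.flatnonzero(~in_set)
        if len(pool) == 0:
            continue
        picks = rng.choice(pool, size=params.n_ctrl_per_gene, replace=True)
        ctrl_sum += X[picks].sum(axis=0)
        n_ctrl_total += params.n_ctrl_per_gene
    set_mean = X[set_rows].mean(axis=0)
    ctrl_mean = ctrl_sum / n_ctrl_total if n_ctrl_total else np.zeros(X.shape[1])
    return set_mean - ctrl_mean


def score_gene_sets(
    cohort_or_matrix,
    gene_sets: dict,
    params: ModuleScoreParams | None = None,
    gene_ids=None,
    cell_ids=None,
) -> pd.DataFrame:
    """Module score for every named set; cells x sets table."""
    params = params or ModuleScoreParams()
    X, genes = _matrix_and_genes(cohort_or_matrix, gene_ids)
    if cell_ids is None and isinstance(cohort_or_matrix, CellCohort):
        cell_ids = cohort_or_matrix.cell_ids
    cols = {}
    for i, (name, gs) in enumerate(gene_sets.items()):
        p = ModuleScoreParams(params.n_bins, params.n_ctrl_per_gene, params.seed + i)
        cols[name] = module_score(X, gs, p, gene_ids=genes)
    return pd.DataFrame(cols, index=cell_ids)


def assign_caf_groups(
    scores_normal: np.ndarray,
    scores_caf: np.ndarray,
    labels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stratify subtypes into normal-like vs CAF-like groups.

    Per subtype, a paired two-sided t test compares the per-cell normal and
    CAF-like module scores; BH adjustment runs across subtypes; the group
    follows the larger mean score, with exactly tied means reported
    "indeterminate".
    """
    scores_normal = np.asarray(scores_normal, float)
    scores_caf = np.asarray(scores_caf, float)
    labels = np.asarray(labels)
    rows = []
    for cl in sorted(pd.unique(labels), key=str):
        mask = labels == cl
        if mask.sum() < 3:
            warnings.warn(f"subtype {cl!r} has <3 cells; excluded")
            continue
        a, b = scores_normal[mask], scores_caf[mask]
        diff = b - a
        if np.allclose(diff.std(), 0.0) and np.allclose(diff.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = st.ttest_rel(b, a)
            if not np.isfinite(p):
                p = 0.0 if diff.std() == 0 else 1.0
        if np.isclose(a.mean(), b.mean()):
            group = "indeterminate"
        else:
            group = "CAF-like" if b.mean() > a.mean() else "normal-like"
        rows.append({"subtype": cl, "mean_normal": a.mean(), "mean_caf": b.mean(),
                     "t": t, "p": p, "group": group, "n_cells": int(mask.sum())})
    table = pd.DataFrame(rows)
    if len(table):
        table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["adj_p"] < alpha
    return table


def state_correlations(
    state_scores: pd.DataFrame,
    labels,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation for every unordered state pair, per subtype.

    Returns the long-form table and the per-subtype count of pairs with
    p < ``alpha``.  16 states yield 16*15/2 = 120 tested pairs.
    """
    if state_scores.shape[1] < 2:
        raise ValueError("need at least 2 states")
    labels = np.asarray(labels)
    states = list(state_scores.columns)
    rows = []
    for cl in sorted(pd.unique(labels), key=str):
        sub = state_scores.loc[labels == cl]
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                a, b = sub[states[i]], sub[states[j]]
                if a.std() == 0 or b.std() == 0:
                    rho, p = np.nan, np.nan
                else:
                    res = st.spearmanr(a, b)
                    rho, p = res.statistic, res.pvalue
                rows.append({"subtype": cl, "state_a": states[i], "state_b": states[j],
                             "scc": rho, "p": p})
    table = pd.DataFrame(rows)
    counts = (
        table.dropna(subset=["p"]).groupby("subtype")["p"].apply(lambda s: int((s < alpha).sum()))
        if len(table) else pd.Series(dtype=int)
    )
    return table, counts


def enrichment_chi_square(labels, condition_groups, alpha: float = 0.05) -> pd.DataFrame:
    """Subtype-vs-group enrichment by 2x2 chi-square with Fisher fallback.

    For every (subtype, group) the 2x2 table (subtype vs rest) x (group vs
    rest) is tested with continuity-corrected chi-square, falling back to
    Fisher's exact test (flagged) when any expected count is below 5;
    BH-adjusted across all tests.
    """
    labels = np.asarray(labels)
    groups = np.asarray(condition_groups)
    subtypes = sorted(pd.unique(labels), key=str)
    conds = sorted(pd.unique(groups), key=str)
    if len(subtypes) < 2 or len(conds) < 2:
        raise ValueError("need at least 2 subtypes and 2 groups")
    rows = []
    for cl in subtypes:
        for g in conds:
            a = int(((labels == cl) & (groups == g)).sum())
            b = int(((labels == cl) & (groups != g)).sum())
            c = int(((labels != cl) & (groups == g)).sum())
            d = int(((labels != cl) & (groups != g)).sum())
            table = np.array([[a, b], [c, d]])
            expected = st.contingency.expected_freq(table)
            if (expected < 5).any():
                p = st.fisher_exact(table, alternative="two-sided")[1]
                stat, method = np.nan, "fisher"
            else:
                stat, p = st.chi2_contingency(table, correction=True)[:2]
                method = "chi2"
            rows.append({"subtype": cl, "group": g, "n": a, "statistic": stat,
                         "p": p, "method": method})
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["adj_p"] < alpha
    return out


__all__ = [
    "ModuleScoreParams",
    "assign_caf_groups",
    "enrichment_chi_square",
    "module_score",
    "score_gene_sets",
    "state_correlations",
]
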