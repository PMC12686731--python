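"""Bulk-cohort association: single-sample enrichment, survival, trait overlap.

Subtype signatures are scored in bulk samples with a rank-weighted
single-sample enrichment statistic (ssGSEA-style); samples split into
high/low groups at the per-set mean score; groups are compared by a
log-rank test implemented from the risk-set definition and by a
multivariate Cox proportional-hazards model; GWAS-derived trait gene
lists are tested against subtype DEGs by one-sided Fisher's exact test,
with a 2x2 concordance test between two association methods.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests

MIN_SET_OVERLAP = 5


def log10_transform(expression: pd.DataFrame) -> pd.DataFrame:
    """log10(x + 1) of a genes x samples expression table."""
    return np.log10(expression + 1.0)


# ------------------------------------------------------------- enrichment

def _single_sample_score(values: np.ndarray, in_set: np.ndarray,
                         symbols: np.ndarray, alpha: float) -> float:
    """Rank-weighted running-sum enrichment of one sample.

    Genes rank descending by value (symbol tie-break); the gene at
    descending position i carries weight (N - i)^alpha (top gene weight
    N^alpha); the score sums the weighted in-set ECDF minus the out-set
    ECDF over all positions.
    """
    order = np.lexsort((symbols, -values))
    n = len(values)
    m = in_set.sum()
    ranked_in = in_set[order]
    w = (n - np.arange(n)).astype(float) ** alpha
    hit_w = np.where(ranked_in, w, 0.0)
    ecdf_in = np.cumsum(hit_w) / hit_w.sum()
    ecdf_out = np.cumsum(~ranked_in) / (n - m)
    return float((ecdf_in - ecdf_out).sum())


def ssgsea_scores(
    bulk_expression: pd.DataFrame,
    gene_sets: dict,
    alpha: float = 0.25,
    rescale: bool = True,
) -> pd.DataFrame:
    """Sample x set enrichment matrix; per-set scores rescaled to [-1, 1].

    Sets overlapping fewer than 5 genes of the expression universe are
    skipped with a warning; constant samples yield missing scores.
    """
    genes = bulk_expression.index.to_numpy().astype(str)
    X = bulk_expression.to_numpy(float)
    out = {}
    for name, gs in gene_sets.items():
        in_set = np.isin(genes, list(gs))
        if in_set.sum() < MIN_SET_OVERLAP:
            warnings.warn(f"set {name!r} overlaps {int(in_set.sum())} genes; skipped")
            continue
        scores = np.full(X.shape[1], np.nan)
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0:
                continue
            scores[j] = _single_sample_score(col, in_set, genes, alpha)
        if rescale:
            finite = np.isfinite(scores)
            if finite.any():
                lo, hi = np.nanmin(scores), np.nanmax(scores)
                if hi > lo:
                    scores = 2.0 * (scores - lo) / (hi - lo) - 1.0
                else:
                    scores = np.where(finite, 0.0, np.nan)
        out[name] = scores
    return pd.DataFrame(out, index=bulk_expression.columns)


def mean_split(enrichment_column) -> pd.Series:
    """Label samples 'high' when strictly above the mean, else 'low'."""
    s = pd.Series(enrichment_column, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 samples")
    labels = pd.Series(np.where(s > s.mean(), "high", "low"), index=s.index)
    if (labels == labels.iloc[0]).all():
        warnings.warn("degenerate mean split: all samples on one side")
    return labels


# --------------------------------------------------------------- survival

def logrank_test(times, events, groups, z: float = 1.959963984540054) -> dict:
    """Two-group log-rank test from the risk-set definition.

    At each distinct event time, observed group-1 events are compared with
    their expectation under the proportional risk-set null; the statistic
    is chi-square(1).  The hazard ratio is the O/E ratio estimator
    (O1/E1)/(O2/E2) with log-HR variance 1/E1 + 1/E2 for the CI.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups), key=str)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    g1 = groups == names[0]
    if g1.all() or not g1.any():
        raise ValueError("each group needs at least one subject")
    if events.sum() == 0:
        raise ValueError("need at least one event")

    o1 = e1 = o2 = e2 = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * (n - n1) / n
        if n > 1:
            var += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    stat = (o1 - e1) ** 2 / var if var > 0 else 0.0
    p = float(st.chi2.sf(stat, df=1)) if var > 0 else 1.0
    if e1 > 0 and e2 > 0 and o1 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
        se = np.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (hr * np.exp(-z * se), hr * np.exp(z * se))
    else:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    return {"statistic": float(stat), "p": p, "hr": float(hr),
            "ci_low": ci[0], "ci_high": ci[1],
            "observed": (o1, o2), "expected": (e1, e2),
            "group_order": names}


def cox_multivariate(times, events, group, covariates=None) -> pd.DataFrame:
    """Multivariate Cox proportional hazards via partial likelihood.

    Returns one row per term with HR, Wald CI and p.  Constant covariates
    and non-converging fits yield flagged rows instead of raising.
    """
    df = pd.DataFrame({"time": np.asarray(times, float),
                       "event": np.asarray(events, int)})
    g = pd.Series(group)
    df["group"] = (g.astype(str) == "high").astype(float).to_numpy() if g.dtype == object else np.asarray(g, float)
    flagged = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for col in cov.columns:
            vals = pd.to_numeric(cov[col], errors="coerce")
            if vals.nunique(dropna=True) <= 1:
                flagged.append({"term": col, "hr": np.nan, "ci_low": np.nan,
                                "ci_high": np.nan, "p": np.nan, "flag": "degenerate"})
                continue
            df[col] = vals.to_numpy()
    terms = [c for c in df.columns if c not in ("time", "event")]
    if df["event"].sum() < len(terms):
        raise ValueError("fewer events than model terms")
    try:
        cph = CoxPHFitter()
        cph.fit(df.dropna(), duration_col="time", event_col="event")
        summ = cph.summary
        rows = [{"term": t,
                 "hr": float(np.exp(summ.loc[t, "coef"])),
                 "ci_low": float(np.exp(summ.loc[t, "coef lower 95%"])),
                 "ci_high": float(np.exp(summ.loc[t, "coef upper 95%"])),
                 "p": float(summ.loc[t, "p"]),
                 "flag": ""} for t in terms]
    except Exception as exc:  # separation / non-convergence
        rows = [{"term": t, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "p": np.nan, "flag": f"non-convergent: {type(exc).__name__}"}
                for t in terms]
    return pd.DataFrame(rows + flagged)


def survival_screen(
    enrichment: pd.DataFrame,
    survival: pd.DataFrame,
    covariate_cols=(),
) -> pd.DataFrame:
    """Mean-split each enrichment column and test survival both ways.

    Emits per set: group sizes, raw log-rank p and O/E hazard ratio, Cox
    model HR/CI/p for the group term, plus BH-adjusted columns.
    """
    rows = []
    for name in enrichment.columns:
        scores = enrichment[name].reindex(survival.index)
        groups = mean_split(scores)
        if groups.nunique() < 2:
            continue
        lr = logrank_test(survival["time"], survival["event"], groups)
        # orient HR as high vs low
        if lr["group_order"][0] == "low":
            lr["hr"], lr["ci_low"], lr["ci_high"] = (
                1.0 / lr["hr"], 1.0 / lr["ci_high"], 1.0 / lr["ci_low"])
        cov = survival[list(covariate_cols)] if covariate_cols else None
        cox = cox_multivariate(survival["time"], survival["event"], groups, cov)
        grow = cox.set_index("term").loc["group"]
        rows.append({
            "set": name,
            "n_high": int((groups == "high").sum()),
            "n_low": int((groups == "low").sum()),
            "logrank_p": lr["p"], "logrank_hr": lr["hr"],
            "logrank_ci_low": lr["ci_low"], "logrank_ci_high": lr["ci_high"],
            "cox_hr": grow["hr"], "cox_ci_low": grow["ci_low"],
            "cox_ci_high": grow["ci_high"], "cox_p": grow["p"],
            "cox_flag": grow["flag"],
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["logrank_adj_p"] = multipletests(out["logrank_p"], method="fdr_bh")[1]
        valid = out["cox_p"].notna()
        out["cox_adj_p"] = np.nan
        if valid.any():
            out.loc[valid, "cox_adj_p"] = multipletests(out.loc[valid, "cox_p"], method="fdr_bh")[1]
    return out


# -------------------------------------------------- signatures and traits

def signature_matrix(cohort_or_matrix, labels, gene_ids=None) -> pd.DataFrame:
    """Genes x subtypes table of mean normalized expression (reference profiles)."""
    from ._types import CellCohort

    if isinstance(cohort_or_matrix, CellCohort):
        X, gene_ids = cohort_or_matrix.normalized, cohort_or_matrix.gene_ids
    else:
        X = cohort_or_matrix
        if gene_ids is None:
            raise ValueError("gene_ids required with a bare matrix")
    labels = np.asarray(labels)
    cols = {}
    for cl in sorted(pd.unique(labels), key=str):
        mask = labels == cl
        if not mask.any():
            warnings.warn(f"subtype {cl!r} empty; column omitted")
            continue
        cols[cl] = X[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(gene_ids))


def trait_overlap(
    trait_gene_lists: dict,
    subtype_degs: dict,
    universe_size: int,
    top_k: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher overlap of trait top-k genes with subtype DEGs.

    One row per trait x subtype with shared-gene count, odds ratio, raw p
    (the screening criterion) and a BH-adjusted column.
    """
    def _genes(obj):
        if isinstance(obj, pd.DataFrame):
            return list(obj["gene"]) if "gene" in obj.columns else list(obj.iloc[:, 0])
        return list(obj)

    rows = []
    for trait, tl in trait_gene_lists.items():
        tset = set(_genes(tl)[:top_k])
        for subtype, dl in subtype_degs.items():
            dset = set(_genes(dl))
            if not dset:
                continue
            if universe_size < len(tset | dset):
                raise ValueError("universe_size smaller than the union of tested genes")
            k = len(tset & dset)
            table = [[k, len(tset) - k],
                     [len(dset) - k, universe_size - len(tset) - len(dset) + k]]
            odds, p = st.fisher_exact(table, alternative="greater")
            rows.append({"trait": trait, "subtype": subtype, "shared": k,
                         "trait_size": len(tset), "deg_size": len(dset),
                         "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] < alpha
    return out


def method_concordance(sig_a, sig_b, n_total: int) -> dict:
    """2x2 concordance of two significant-association sets over n_total tests.

    Table [[|A∩B|, |A\\B|], [|B\\A|, n - |A∪B|]], one-sided Fisher
    (enrichment) with the odds ratio.
    """
    a, b = set(sig_a), set(sig_b)
    if n_total < len(a | b):
        raise ValueError("n_total smaller than the union of associations")
    inter = len(a & b)
    table = [[inter, len(a) - inter], [len(b) - inter, n_total - len(a | b)]]
    odds, p = st.fisher_exact(table, alternative="greater")
    return {"table": table, "odds_ratio": float(odds), "p": float(p),
            "n_concordant": inter}


__all__ = [
    "cox_multivariate",
    "log10_transform",
    "logrank_test",
    "mean_split",
    "method_concordance",
    "signature_matrix",
    "ssgsea_scores",
    "survival_screen",
    "trait_overlap",
]
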