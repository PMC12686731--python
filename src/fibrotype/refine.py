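"""Subtype refinement: resolution scan, purity-guided merging, diagnostics.

The refinement recipe is: build a kNN graph on the top principal
components of the HVG log-normalized matrix; run Louvain-style modularity
community detection over a grid of resolutions; pick the resolution with
the highest median cluster purity (an entropy-based ROGUE-style statistic,
with batch mixing reported via LISI); then coarsen in two stages —
clusters sharing enough of their top differentially expressed genes are
merged first, and remaining pairs are merged greedily whenever the merged
cluster is purer than both parents.

Purity statistic: within a cluster, a gene's expression entropy across
cells is compared with the value expected for its mean expression (a
LOESS-like fit of entropy on log mean expression across genes).  Genes
whose entropy falls significantly below the fit (one-sided test against a
null calibrated on the non-deficient genes, BH-adjusted at 0.05) signal
heterogeneity; purity = 1 - D/(D + K) where D is the summed significant
entropy deficit and K a scale constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from ._types import CellCohort, ClusterState

MIN_PURITY_CELLS = 20


@dataclass
class RefineParams:
    resolution_grid: tuple = tuple(np.round(np.arange(0.0, 3.01, 0.1), 2))
    n_neighbors: int = 15
    n_pcs: int = 30
    lisi_perplexity: float = 30.0
    rogue_K: float = 45.0
    top_n_deg: int = 20
    min_shared_deg: int = 5
    deg_min_log2fc: float = 1.0
    deg_max_adj_p: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if any(r < 0 for r in self.resolution_grid):
            raise ValueError("resolutions must be >= 0")
        if self.min_shared_deg > self.top_n_deg:
            raise ValueError("min_shared_deg must be <= top_n_deg")
        if self.rogue_K <= 0:
            raise ValueError("rogue_K must be > 0")


# ---------------------------------------------------------------- embedding

def pca_embedding(normalized: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Cells x n_pcs PCA embedding of a genes x cells matrix (genes centered)."""
    X = normalized.T
    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n_pcs_eff}")
    return PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(
        X - X.mean(axis=0)
    )


def _knn_graph(embedding: np.ndarray, n_neighbors: int) -> ig.Graph:
    n = embedding.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    return ig.Graph(n=n, edges=sorted(edges), directed=False)


def cluster_at_resolutions(
    embedding: np.ndarray,
    params: RefineParams,
) -> tuple[pd.DataFrame, dict]:
    """Community detection at every grid resolution on a shared kNN graph.

    Returns (resolution_table, {resolution: integer label array}); purity
    and LISI columns are filled in by the pipeline driver.
    """
    params.validate()
    if embedding.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    graph = _knn_graph(embedding, params.n_neighbors)
    labels, rows = {}, []
    for res in params.resolution_grid:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res),
            seed=params.seed,
        )
        lab = np.array(part.membership)
        labels[res] = lab
        rows.append({"resolution": res, "n_clusters": int(lab.max() + 1)})
    table = pd.DataFrame(rows).sort_values("resolution").reset_index(drop=True)
    return table, labels


# --------------------------------------------------------------------- LISI

def compute_lisi(
    embedding: np.ndarray,
    batch_labels,
    perplexity: float = 30.0,
    tol: float = 1e-5,
) -> np.ndarray:
    """Local inverse Simpson index: effective number of batches per cell.

    Gaussian kernel weights over the 3*perplexity nearest neighbors are
    calibrated per cell to the target perplexity by bisection on the
    kernel precision; LISI = 1 / sum_b p(b)^2 of the weighted batch
    proportions, ranging from 1 to the number of batches.  The Simpson
    sum uses the unbiased weighted estimator
    (sum_b phat_b^2 - sum_j w_j^2) / (1 - sum_j w_j^2), removing the
    finite-neighborhood bias of the plug-in estimate.
    """
    batches = pd.Categorical(np.asarray(batch_labels))
    n = embedding.shape[0]
    if len(batches.categories) == 1:
        return np.ones(n)
    k = int(min(3 * perplexity, n - 1))
    if n < perplexity + 1:
        raise ValueError("need at least perplexity+1 cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]
    d2 = dist**2
    target = np.log(perplexity)
    codes = np.asarray(batches.codes)
    n_batch = len(batches.categories)
    lisi = np.ones(n)
    for i in range(n):
        lo, hi, beta = 0.0, np.inf, 1.0
        for _ in range(64):
            w = np.exp(-beta * d2[i])
            s = w.sum()
            if s <= 0:
                beta /= 2
                continue
            p = w / s
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(h - target) < tol:
                break
            if h > target:  # too flat -> sharpen
                lo, beta = beta, (beta * 2 if not np.isfinite(hi) else (beta + hi) / 2)
            else:
                hi, beta = beta, (beta + lo) / 2
        w = np.exp(-beta * d2[i])
        p = w / w.sum() if w.sum() > 0 else np.full(k, 1.0 / k)
        props = np.bincount(codes[idx[i]], weights=p, minlength=n_batch)
        w2 = np.square(p).sum()
        simpson = (np.square(props).sum() - w2) / max(1.0 - w2, 1e-12)
        lisi[i] = 1.0 / np.clip(simpson, 1.0 / n_batch, 1.0)
    return lisi


# ------------------------------------------------------------------- purity

def _entropy_deficit(expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (E, S): log mean expression and expression entropy across cells."""
    mean = expr.mean(axis=1)
    E = np.log(mean + 1.0)
    total = expr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, expr / np.maximum(total, 1e-300), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = -plogp.sum(axis=1)
    return E, S


def _local_null_sd(resid: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Entropy-noise sd as a function of E, from the mirrored r<=0 genes."""
    nonpos = resid <= 0
    if nonpos.sum() < 5:
        pooled = float(np.sqrt(np.mean(resid**2))) if len(resid) else 1.0
        return np.full(len(E), max(pooled, 1e-6))
    var_fit = lowess(resid[nonpos] ** 2, E[nonpos], frac=0.5,
                     return_sorted=False, xvals=E)
    return np.sqrt(np.clip(var_fit, 1e-12, None))


def _purity_from_cells(
    expr: np.ndarray,
    rogue_K: float,
    alpha: float = 0.05,
    min_mean: float = 1.0,
    n_refit: int = 2,
) -> float:
    """Purity of one cell group from its expm1-normalized expression block.

    Genes below ``min_mean`` average expression are excluded: their entropy
    estimates carry a heavy-tailed sampling skew that would dominate the
    deficit sum.  The S(E) baseline is refitted after trimming strongly
    deficient genes so that a heterogeneity band cannot drag the curve
    toward itself.
    """
    keep = expr.mean(axis=1) >= min_mean
    if keep.sum() < 10:
        return 1.0 if expr.sum() > 0 else float("nan")
    E, S = _entropy_deficit(expr[keep])
    if np.ptp(E) == 0:
        return 1.0
    fit = lowess(S, E, frac=0.5, return_sorted=False)
    for _ in range(n_refit):
        resid = fit - S  # positive = entropy deficit
        sd = _local_null_sd(resid, E)
        ok = resid <= 2.5 * sd
        if ok.all() or ok.sum() < 10:
            break
        fit = lowess(S[ok], E[ok], frac=0.5, return_sorted=False, xvals=E)
    resid = fit - S
    sd = _local_null_sd(resid, E)
    z = resid / sd
    # one-sided test against the empirical null formed by mirroring the
    # non-deficient genes; a lone outlier cannot reach significance, so a
    # homogeneous cluster yields D = 0 and purity exactly 1
    null = np.sort(-z[z <= 0])
    if len(null) == 0:
        sig = z > 0
    else:
        exceed = len(null) - np.searchsorted(null, z, side="left")
        pvals = np.where(z > 0, (1.0 + exceed) / (1.0 + len(null)), 1.0)
        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0] & (z > 0)
    D = float(resid[sig].sum()) if sig.any() else 0.0
    return 1.0 - D / (D + rogue_K)


def compute_purity(
    cohort_or_matrix,
    labels,
    rogue_K: float = 45.0,
    sample_labels=None,
) -> pd.Series:
    """ROGUE-style purity per cluster, in [0, 1]; NaN when not computable.

    When ``sample_labels`` is given, the statistic is computed within each
    sample holding >= 20 of the cluster's cells and averaged across those
    samples; otherwise it is computed on the pooled cluster.
    """
    X = cohort_or_matrix.normalized if isinstance(cohort_or_matrix, CellCohort) else cohort_or_matrix
    if X is None:
        raise ValueError("normalized matrix required")
    expr = np.expm1(X)
    labels = np.asarray(labels)
    out = {}
    samp = None if sample_labels is None else np.asarray(sample_labels)
    for cl in pd.unique(labels):
        mask = labels == cl
        if mask.sum() < MIN_PURITY_CELLS:
            warnings.warn(f"cluster {cl!r} has <{MIN_PURITY_CELLS} cells; purity missing")
            out[cl] = float("nan")
            continue
        if samp is not None:
            vals = []
            for s in pd.unique(samp[mask]):
                sm = mask & (samp == s)
                if sm.sum() >= MIN_PURITY_CELLS:
                    vals.append(_purity_from_cells(expr[:, sm], rogue_K))
            out[cl] = float(np.nanmean(vals)) if vals else _purity_from_cells(expr[:, mask], rogue_K)
        else:
            out[cl] = _purity_from_cells(expr[:, mask], rogue_K)
    return pd.Series(out, name="purity")


# --------------------------------------------------------------------- DEGs

def rank_degs(
    cohort_or_matrix,
    labels,
    gene_ids=None,
    min_log2fc: float = 1.0,
    max_adj_p: float = 0.01,
) -> dict:
    """One-vs-rest Wilcoxon DEGs per cluster, ranked by log2 fold change.

    log2FC compares mean(expm1(normalized)) + 1 between the cluster and the
    rest; genes pass at log2FC > ``min_log2fc`` and BH-adjusted p <
    ``max_adj_p``; ties break by adjusted p then symbol.
    """
    if isinstance(cohort_or_matrix, CellCohort):
        X, gene_ids = cohort_or_matrix.normalized, cohort_or_matrix.gene_ids
    else:
        X = cohort_or_matrix
        if gene_ids is None:
            raise ValueError("gene_ids required with a bare matrix")
    gene_ids = pd.Index(gene_ids)
    labels = np.asarray(labels)
    expr = np.expm1(X)
    out = {}
    for cl in pd.unique(labels):
        mask = labels == cl
        if mask.sum() < 3 or (~mask).sum() < 3:
            warnings.warn(f"cluster {cl!r} too small for DEG testing")
            out[cl] = _empty_deg_frame()
            continue
        a, b = X[:, mask], X[:, ~mask]
        with np.errstate(invalid="ignore"):
            res = st.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.nan_to_num(res.pvalue, nan=1.0)
        log2fc = np.log2((expr[:, mask].mean(axis=1) + 1.0) /
                         (expr[:, ~mask].mean(axis=1) + 1.0))
        adj_p = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame({"gene": gene_ids, "log2fc": log2fc, "p": p, "adj_p": adj_p})
        df = df[(df.log2fc > min_log2fc) & (df.adj_p < max_adj_p)]
        df = df.sort_values(["log2fc", "adj_p", "gene"],
                            ascending=[False, True, True], kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        out[cl] = df.reset_index(drop=True)
    return out


def _empty_deg_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "log2fc", "p", "adj_p", "rank"])


# ------------------------------------------------------------------ merging

def shared_deg_components(deg_lists: dict, top_n_deg: int, min_shared_deg: int) -> dict:
    """Map cluster -> merged-component id by transitive closure of the
    'share >= min_shared of the top-n DEGs' relation."""
    clusters = sorted(deg_lists, key=str)
    tops = {c: set(deg_lists[c]["gene"].head(top_n_deg)) for c in clusters}
    parent = {c: c for c in clusters}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            if len(tops[a] & tops[b]) >= min_shared_deg:
                parent[find(a)] = find(b)
    return {c: find(c) for c in clusters}


def merge_by_shared_degs(
    labels,
    deg_lists: dict,
    top_n_deg: int = 20,
    min_shared_deg: int = 5,
    recompute=None,
    max_rounds: int = 10,
) -> np.ndarray:
    """Merge clusters sharing >= ``min_shared_deg`` of their top DEGs.

    Connected components of the sharing graph merge together within a
    round; with ``recompute`` (a labels -> deg_lists callable) DEGs are
    refreshed and rounds repeat until no edge remains.
    """
    labels = np.asarray(labels).copy()
    for _ in range(max_rounds):
        comp = shared_deg_components(deg_lists, top_n_deg, min_shared_deg)
        if all(comp[c] == c for c in comp):
            break
        labels = np.array([comp.get(l, l) for l in labels])
        if recompute is None:
            break
        deg_lists = recompute(labels)
    return labels


def merge_by_purity_gain(
    cohort_or_matrix,
    labels,
    rogue_K: float = 45.0,
    sample_labels=None,
    gene_ids=None,
) -> np.ndarray:
    """Greedily merge cluster pairs whose union is purer than both parents.

    Candidate pairs are visited in descending Spearman correlation of their
    mean expression profiles; after each accepted merge, purities and
    correlations are recomputed.
    """
    X = cohort_or_matrix.normalized if isinstance(cohort_or_matrix, CellCohort) else cohort_or_matrix
    if isinstance(cohort_or_matrix, CellCohort) and sample_labels is None:
        sample_labels = cohort_or_matrix.cell_meta["sample"].to_numpy()
    labels = np.asarray(labels).copy()
    expr = np.expm1(X)
    samp = None if sample_labels is None else np.asarray(sample_labels)

    def group_purity(mask: np.ndarray) -> float:
        if mask.sum() < MIN_PURITY_CELLS:
            return float("nan")
        if samp is not None:
            vals = [
                _purity_from_cells(expr[:, mask & (samp == s)], rogue_K)
                for s in pd.unique(samp[mask])
                if (mask & (samp == s)).sum() >= MIN_PURITY_CELLS
            ]
            if vals:
                return float(np.nanmean(vals))
        return _purity_from_cells(expr[:, mask], rogue_K)

    while True:
        clusters = sorted(pd.unique(labels), key=str)
        if len(clusters) < 2:
            break
        profiles = np.column_stack([X[:, labels == c].mean(axis=1) for c in clusters])
        pur = {c: group_purity(labels == c) for c in clusters}
        pairs = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                rho = st.spearmanr(profiles[:, i], profiles[:, j]).statistic
                pairs.append((rho, clusters[i], clusters[j]))
        pairs.sort(key=lambda t: (-(t[0] if np.isfinite(t[0]) else -2), str(t[1]), str(t[2])))
        merged = False
        for _, a, b in pairs:
            pm = group_purity((labels == a) | (labels == b))
            # >= rather than >: homogeneous groups saturate at purity 1.0,
            # so exact ties mean "no detectable heterogeneity gained"
            if np.isfinite(pm) and pm >= pur[a] and pm >= pur[b]:
                labels[labels == b] = a
                merged = True
                break
        if not merged:
            break
    return labels


# ------------------------------------------------------------- similarity

def cluster_similarity(cohort_or_matrix, labels, gene_ids=None, linkage: str = "complete"):
    """Spearman correlation of cluster mean profiles + dendrogram leaf order."""
    X = cohort_or_matrix.normalized if isinstance(cohort_or_matrix, CellCohort) else cohort_or_matrix
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels), key=str)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    profiles = np.column_stack([X[:, labels == c].mean(axis=1) for c in clusters])
    scc = pd.DataFrame(np.eye(len(clusters)), index=clusters, columns=clusters)
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if profiles[:, i].std() == 0 or profiles[:, j].std() == 0:
                rho = np.nan
            else:
                rho = st.spearmanr(profiles[:, i], profiles[:, j]).statistic
            scc.iloc[i, j] = scc.iloc[j, i] = rho
    dist = 1.0 - np.nan_to_num(scc.to_numpy(), nan=0.0)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(clusters), 1)]
    order = sch.leaves_list(sch.linkage(condensed, method=linkage))
    return scc, [clusters[i] for i in order]


# ------------------------------------------------------------ full pipeline

def refine_pipeline(
    cohort: CellCohort,
    params: RefineParams | None = None,
    batch_labels=None,
    hvg=None,
) -> ClusterState:
    """Resolution scan -> purity-selected resolution -> two-stage merge.

    The kNN-graph embedding uses the HVG rows (all genes when ``hvg`` is
    None); purity, DEGs and merge decisions use the full normalized
    matrix, since HVG selection skews the gene composition the entropy
    statistic relies on.  Resolution choice maximizes median cluster
    purity; batch-mixing LISI is reported alongside.
    """
    params = params or RefineParams()
    params.validate()
    X = cohort.normalized
    if X is None:
        raise ValueError("call normalize_log first")
    emb_rows = (
        np.asarray(cohort.gene_ids.isin(pd.Index(hvg)))
        if hvg is not None
        else np.ones(cohort.n_genes, bool)
    )
    emb = pca_embedding(X[emb_rows], params.n_pcs, params.seed)
    table, labelsets = cluster_at_resolutions(emb, params)

    if batch_labels is None:
        batch_labels = cohort.cell_meta["batch"].to_numpy()
    if len(pd.unique(batch_labels)) > 1 and X.shape[1] > params.lisi_perplexity:
        median_lisi = float(np.median(compute_lisi(emb, batch_labels, params.lisi_perplexity)))
    else:
        median_lisi = 1.0
    table["median_lisi"] = median_lisi

    med_purity = []
    for res in table["resolution"]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pur = compute_purity(X, labelsets[res], params.rogue_K)
        med_purity.append(float(pur.median(skipna=True)) if pur.notna().any() else np.nan)
    table["median_purity"] = med_purity

    best = table.loc[table["median_purity"].idxmax(), "resolution"]
    labels = labelsets[best].copy()

    def recompute(lab):
        return rank_degs(X, lab, cohort.gene_ids, params.deg_min_log2fc, params.deg_max_adj_p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        degs = recompute(labels)
        labels = merge_by_shared_degs(labels, degs, params.top_n_deg,
                                      params.min_shared_deg, recompute=recompute)
        labels = merge_by_purity_gain(
            X, labels, params.rogue_K,
            sample_labels=cohort.cell_meta["sample"].to_numpy(),
        )
        final_degs = recompute(labels)
        purity = compute_purity(X, labels, params.rogue_K)

    clusters = sorted(pd.unique(labels), key=str)
    profiles = pd.DataFrame(
        np.column_stack([X[:, labels == c].mean(axis=1) for c in clusters]),
        index=cohort.gene_ids, columns=clusters,
    )
    return ClusterState(
        labels=pd.Series(labels, index=cohort.cell_ids, name="cluster"),
        purity=purity,
        degs=final_degs,
        profiles=profiles,
        resolution_table=table,
    )


__all__ = [
    "RefineParams",
    "cluster_at_resolutions",
    "cluster_similarity",
    "compute_lisi",
    "compute_purity",
    "merge_by_purity_gain",
    "merge_by_shared_degs",
    "pca_embedding",
    "rank_degs",
    "refine_pipeline",
    "shared_deg_components",
]
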