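"""Clustering scan, LISI, purity statistic, DEGs, and the merge rules."""

import numpy as np
import pandas as pd
import pytest

from fibrotype import qc
from fibrotype.refine import (
    RefineParams,
    cluster_at_resolutions,
    cluster_similarity,
    compute_lisi,
    compute_purity,
    merge_by_purity_gain,
    merge_by_shared_degs,
    pca_embedding,
    rank_degs,
    shared_deg_components,
)
from fibrotype.simulate import SimConfig, generate_cohort


# ------------------------------------------------------------ clustering

def test_single_resolution_gives_single_labeling(planted2_small):
    emb = pca_embedding(planted2_small.cohort.normalized, 10, seed=0)
    params = RefineParams(resolution_grid=(1.0,), seed=0)
    table, labels = cluster_at_resolutions(emb, params)
    assert len(table) == 1 and set(labels) == {1.0}


def test_resolution_scan_recovers_planted_subtypes(planted3):
    from sklearn.metrics import adjusted_rand_score

    co = planted3.cohort
    emb = pca_embedding(co.normalized, 20, seed=1)
    grid = tuple(np.round(np.arange(0.2, 1.61, 0.2), 2))
    table, labels = cluster_at_resolutions(emb, RefineParams(resolution_grid=grid, seed=1))
    truth = planted3.truth_subtype.to_numpy()
    aris = [adjusted_rand_score(truth, labels[r]) for r in grid
            if labels[r].max() + 1 >= 3]
    assert max(aris) >= 0.9
    # cluster count non-decreasing for >=90% of adjacent grid pairs
    n = table["n_clusters"].to_numpy()
    frac = np.mean(np.diff(n) >= 0)
    assert frac >= 0.9


# ------------------------------------------------------------------ LISI

def test_lisi_single_batch_is_one(rng):
    emb = rng.normal(size=(300, 4))
    assert (compute_lisi(emb, ["b"] * 300, 20.0) == 1.0).all()


def test_lisi_interleaved_batches_approach_two(rng):
    emb = rng.normal(size=(2000, 5))
    batches = np.tile(["a", "b"], 1000)
    lisi = compute_lisi(emb, batches, 30.0)
    assert abs(lisi.mean() - 2.0) < 0.1


def test_lisi_separated_batches_stay_near_one(rng):
    a = rng.normal(0.0, 1.0, (500, 3))
    b = rng.normal(20.0, 1.0, (500, 3))
    lisi = compute_lisi(np.vstack([a, b]), ["a"] * 500 + ["b"] * 500, 30.0)
    assert lisi.mean() < 1.1


# ---------------------------------------------------------------- purity

def test_purity_constant_genes_give_one():
    X = np.log1p(np.tile(np.arange(1, 31)[:, None], (1, 40)).astype(float))
    pur = compute_purity(X, np.zeros(40, int), rogue_K=45.0)
    assert pur[0] == pytest.approx(1.0)


def test_purity_k_limit_is_one(planted2_small):
    syn = planted2_small
    truth = syn.truth_subtype.to_numpy()
    # K -> infinity drives the mixture's (nonzero-deficit) purity to 1
    n0 = np.flatnonzero(truth == "subtype_0")[:300]
    n1 = np.flatnonzero(truth == "subtype_1")[:300]
    lab = np.full(len(truth), "rest", dtype=object)
    lab[n0] = lab[n1] = "mix"
    small = compute_purity(syn.cohort.normalized, lab, rogue_K=45.0)["mix"]
    large = compute_purity(syn.cohort.normalized, lab, rogue_K=1e12)["mix"]
    assert small < 1.0
    assert large > small
    assert large == pytest.approx(1.0, abs=1e-6)


def test_purity_in_unit_interval(planted2_small):
    pur = compute_purity(planted2_small.cohort.normalized,
                         planted2_small.truth_subtype.to_numpy(), 45.0)
    assert ((pur >= 0) & (pur <= 1)).all()


def test_mixture_is_less_pure_than_either_subtype(planted2_small):
    syn = planted2_small
    truth = syn.truth_subtype.to_numpy()
    X = syn.cohort.normalized
    pure = compute_purity(X, truth, 45.0)
    n0 = np.flatnonzero(truth == "subtype_0")[:300]
    n1 = np.flatnonzero(truth == "subtype_1")[:300]
    lab = np.full(len(truth), "rest", dtype=object)
    lab[n0] = lab[n1] = "mix"
    mixed = compute_purity(X, lab, 45.0)["mix"]
    assert mixed < pure["subtype_0"]
    assert mixed < pure["subtype_1"]


def test_purity_decreases_with_contamination(planted2_small):
    syn = planted2_small
    truth = syn.truth_subtype.to_numpy()
    X = syn.cohort.normalized
    base = np.flatnonzero(truth == "subtype_0")[:400]
    foreign = np.flatnonzero(truth == "subtype_1")
    vals = []
    for n_foreign in (0, 100, 300):
        lab = np.full(len(truth), "rest", dtype=object)
        lab[base] = "c"
        lab[foreign[:n_foreign]] = "c"
        vals.append(compute_purity(X, lab, 45.0)["c"])
    assert vals[0] > vals[1] > vals[2]


def test_purity_missing_for_tiny_cluster(planted2_small):
    lab = np.zeros(planted2_small.cohort.n_cells, int)
    lab[:5] = 1
    with pytest.warns(UserWarning, match="purity missing"):
        pur = compute_purity(planted2_small.cohort.normalized, lab, 45.0)
    assert np.isnan(pur[1])


# ------------------------------------------------------------------ DEGs

def test_planted_markers_appear_in_own_deg_list():
    cfg = SimConfig(n_genes=1000, n_cells=800, n_subtypes=2,
                    markers_per_subtype=40, marker_log2fc=2.5, n_batches=1, seed=1)
    syn = generate_cohort(cfg)
    co = qc.normalize_log(syn.cohort)
    degs = rank_degs(co, syn.truth_subtype.to_numpy())
    for k in range(2):
        found = set(degs[f"subtype_{k}"]["gene"])
        markers = set(syn.truth_markers[f"subtype_{k}"])
        assert len(markers & found) / len(markers) > 0.8


def test_null_split_yields_empty_deg_lists():
    empties = 0
    for seed in range(20):
        cfg = SimConfig(n_genes=300, n_cells=400, n_subtypes=1, markers_per_subtype=0,
                        marker_log2fc=0.0, n_batches=1, seed=seed)
        co = qc.normalize_log(generate_cohort(cfg).cohort)
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, co.n_cells)
        degs = rank_degs(co, labels)
        if all(len(df) == 0 for df in degs.values()):
            empties += 1
    assert empties >= 19


def test_zero_count_gene_never_a_deg(planted2_small):
    syn = planted2_small
    co = syn.cohort.copy()
    co.normalized = co.normalized.copy()
    co.normalized[0, :] = 0.0
    degs = rank_degs(co.normalized, syn.truth_subtype.to_numpy(), co.gene_ids)
    gene0 = co.gene_ids[0]
    assert all(gene0 not in set(df["gene"]) for df in degs.values())


# --------------------------------------------------------------- merging

def _fake_degs(tops):
    return {c: pd.DataFrame({"gene": genes, "log2fc": np.linspace(5, 1, len(genes)),
                             "p": 0.0, "adj_p": 0.0, "rank": range(1, len(genes) + 1)})
            for c, genes in tops.items()}


def test_merge_at_exactly_five_shared_degs():
    shared = [f"S{i}" for i in range(5)]
    degs = _fake_degs({
        "A": shared + [f"A{i}" for i in range(15)],
        "B": shared + [f"B{i}" for i in range(15)],
    })
    labels = np.array(["A"] * 10 + ["B"] * 10)
    merged = merge_by_shared_degs(labels, degs, 20, 5)
    assert len(set(merged)) == 1


def test_no_merge_below_threshold():
    shared = [f"S{i}" for i in range(4)]
    degs = _fake_degs({
        "A": shared + [f"A{i}" for i in range(16)],
        "B": shared + [f"B{i}" for i in range(16)],
    })
    labels = np.array(["A"] * 10 + ["B"] * 10)
    merged = merge_by_shared_degs(labels, degs, 20, 5)
    assert len(set(merged)) == 2


def test_chain_merges_transitively_in_one_round():
    sab = [f"AB{i}" for i in range(5)]
    sbc = [f"BC{i}" for i in range(5)]
    degs = _fake_degs({
        "A": sab + [f"A{i}" for i in range(15)],
        "B": sab + sbc + [f"B{i}" for i in range(10)],
        "C": sbc + [f"C{i}" for i in range(15)],
    })
    comp = shared_deg_components(degs, 20, 5)
    assert len(set(comp.values())) == 1  # A-B-C one component, A∩C empty


def test_merge_only_coarsens(planted2_small):
    syn = planted2_small
    truth = syn.truth_subtype.to_numpy()
    rng = np.random.default_rng(0)
    sub = np.where(rng.random(len(truth)) < 0.5, "_x", "_y")
    labels = np.char.add(truth.astype(str), sub)
    degs = rank_degs(syn.cohort.normalized, labels, syn.cohort.gene_ids)
    merged = merge_by_shared_degs(labels, degs, 20, 5)
    # every merged cluster is a union of input clusters
    for m in set(merged):
        inputs = set(labels[merged == m])
        for i in inputs:
            assert set(merged[labels == i]) == {m}


def test_purity_gain_merges_random_split_of_homogeneous_population(planted2_small):
    syn = planted2_small
    truth = syn.truth_subtype.to_numpy()
    X = syn.cohort.normalized
    mask = truth == "subtype_0"
    Xs = X[:, mask]
    rng = np.random.default_rng(1)
    halves = np.where(rng.random(mask.sum()) < 0.5, "h1", "h2")
    merged = merge_by_purity_gain(Xs, halves, 45.0)
    assert len(set(merged)) == 1


def test_purity_gain_keeps_separated_subtypes(planted2_small):
    syn = planted2_small
    merged = merge_by_purity_gain(syn.cohort.normalized,
                                  syn.truth_subtype.to_numpy(), 45.0)
    assert len(set(merged)) == 2


def test_purity_gain_single_cluster_identity(planted2_small):
    lab = np.zeros(planted2_small.cohort.n_cells, int)
    merged = merge_by_purity_gain(planted2_small.cohort.normalized, lab, 45.0)
    assert (merged == lab).all()


# ------------------------------------------------------------ similarity

def test_similarity_duplicated_profiles_and_symmetry(planted2_small):
    syn = planted2_small
    truth = syn.truth_subtype.to_numpy()
    # duplicate subtype_0 under two labels
    lab = truth.copy().astype(object)
    half = np.flatnonzero(truth == "subtype_0")
    lab[half[: len(half) // 2]] = "dup"
    scc, order = cluster_similarity(syn.cohort.normalized, lab)
    assert np.allclose(scc, scc.T, equal_nan=True)
    assert np.allclose(np.diag(scc), 1.0)
    assert scc.loc["dup", "subtype_0"] > scc.loc["dup", "subtype_1"]
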