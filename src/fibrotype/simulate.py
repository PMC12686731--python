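"""Synthetic single-cell and bulk cohorts with known planted structure.

The single-cell generator draws gene-wise negative-binomial counts with
variance ``mean + mean**2 / dispersion``.  The per-cell mean is a product of

* a log-normal baseline per gene,
* a ``2**marker_log2fc`` boost for each subtype's disjoint marker block,
* a per-(batch, gene) multiplicative log-normal batch factor,
* an ``exp(slope * age_code)`` trend for each planted age-trend set
  (age codes 0/1/2 for fetal/adult/elderly), and
* a log-normal(0, 0.3) per-cell library-size factor.

The bulk generator ties an exponential event-time hazard to a latent
standard-normal signature activity ``z`` with hazard ratio
``hazard_ratio_per_sd ** z``, shifting the signature genes' log-expression
by ``enrichment_effect * z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._types import CellCohort, InvalidConfigError

DEFAULT_AGE_GROUPS = (("fetal", 0.2), ("adult", 0.5), ("elderly", 0.3))
LIBRARY_SIZE_LOGSD = 0.3


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_cells: int = 3000
    n_subtypes: int = 3
    markers_per_subtype: int = 50
    marker_log2fc: float = 2.0
    baseline_mean_logmu: float = -1.0
    baseline_mean_logsd: float = 1.0
    nb_dispersion: float = 2.0
    n_batches: int = 2
    batch_effect_sd: float = 0.15
    age_groups: tuple = DEFAULT_AGE_GROUPS
    n_trend_sets: int = 0
    trend_genes_per_set: int = 50
    trend_slope: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_subtypes) <= 0:
            raise InvalidConfigError("n_genes, n_cells, n_subtypes must be positive")
        if self.n_subtypes * self.markers_per_subtype > self.n_genes:
            raise InvalidConfigError("marker blocks exceed the gene universe")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if self.n_batches <= 0:
            raise InvalidConfigError("n_batches must be positive")
        props = [p for _, p in self.age_groups]
        if abs(sum(props) - 1.0) > 1e-8 or any(p < 0 for p in props):
            raise InvalidConfigError("age-group proportions must be >=0 and sum to 1")
        if self.n_trend_sets * self.trend_genes_per_set > self.n_genes:
            raise InvalidConfigError("trend sets exceed the gene universe")


@dataclass
class SyntheticCohort:
    cohort: CellCohort
    truth_subtype: pd.Series
    truth_markers: dict
    truth_trend_sets: dict
    trend_signs: dict = field(default_factory=dict)


@dataclass
class BulkSimConfig:
    n_samples: int = 200
    signature: tuple = ()
    n_genes: int = 1000
    gene_universe: tuple = ()  # optional explicit universe containing the signature
    enrichment_effect: float = 1.0
    hazard_ratio_per_sd: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    covariates: tuple = ()  # (name, effect) pairs; effect on log-hazard per sd
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise InvalidConfigError("n_samples must be positive")
        if len(self.signature) == 0:
            raise InvalidConfigError("signature gene set must be nonempty")
        if self.hazard_ratio_per_sd <= 0:
            raise InvalidConfigError("hazard_ratio_per_sd must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise InvalidConfigError("censor_rate must lie in [0, 1]")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a synthetic single-cell cohort with planted subtype structure.

    Identical configs (including seed) yield bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, C = config.n_genes, config.n_cells

    gene_ids = pd.Index([f"G{i:05d}" for i in range(G)])
    baseline = rng.lognormal(config.baseline_mean_logmu, config.baseline_mean_logsd, G)

    subtype = rng.integers(0, config.n_subtypes, C)
    batch = rng.integers(0, config.n_batches, C)
    age_names = [n for n, _ in config.age_groups]
    age_props = np.array([p for _, p in config.age_groups])
    age_code = rng.choice(len(age_names), size=C, p=age_props)

    # marker and trend genes are scattered over the gene universe so that
    # planted sets are not confounded with symbol order or gene index
    n_marker = config.n_subtypes * config.markers_per_subtype
    n_trend = config.n_trend_sets * config.trend_genes_per_set
    if n_marker + n_trend > G:
        raise InvalidConfigError("marker plus trend sets exceed the gene universe")
    special = rng.permutation(G)
    marker_rows = {
        f"subtype_{k}": np.sort(special[k * config.markers_per_subtype:
                                        (k + 1) * config.markers_per_subtype])
        for k in range(config.n_subtypes)
    }
    markers = {name: [f"G{i:05d}" for i in rows] for name, rows in marker_rows.items()}
    trend_sets, trend_signs, trend_rows = {}, {}, {}
    for s in range(config.n_trend_sets):
        lo = n_marker + s * config.trend_genes_per_set
        rows = np.sort(special[lo:lo + config.trend_genes_per_set])
        trend_rows[f"trend_{s}"] = rows
        trend_sets[f"trend_{s}"] = [f"G{i:05d}" for i in rows]
        trend_signs[f"trend_{s}"] = 1.0 if s % 2 == 0 else -1.0

    log_mean = np.log(baseline)[:, None] + np.zeros((G, C))
    fc = config.marker_log2fc * np.log(2.0)
    for k in range(config.n_subtypes):
        rows = marker_rows[f"subtype_{k}"]
        log_mean[np.ix_(rows, subtype == k)] += fc

    batch_fx = rng.normal(0.0, config.batch_effect_sd, (config.n_batches, G))
    log_mean += batch_fx[batch].T

    for s in trend_sets:
        rows = trend_rows[s]
        log_mean[np.ix_(rows, np.arange(C))] += (
            trend_signs[s] * config.trend_slope * age_code[None, :]
        )

    libsize = rng.lognormal(0.0, LIBRARY_SIZE_LOGSD, C)
    mean = np.exp(log_mean) * libsize[None, :]
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    cell_ids = pd.Index([f"cell_{i:06d}" for i in range(C)])
    meta = pd.DataFrame(
        {
            "sample": [f"sample_{b}" for b in batch],
            "tissue": "synthetic",
            "condition": "simulated",
            "batch": [f"batch_{b}" for b in batch],
            "age_group": [age_names[a] for a in age_code],
        },
        index=cell_ids,
    )
    cohort = CellCohort(sp.csr_matrix(counts), gene_ids, meta)
    truth = pd.Series([f"subtype_{k}" for k in subtype], index=cell_ids, name="subtype")
    return SyntheticCohort(cohort, truth, markers, trend_sets, trend_signs)


def generate_bulk_survival(config: BulkSimConfig):
    """Generate a bulk expression table plus survival records.

    Returns ``(expression, survival)``: expression is genes x samples
    (linear scale), survival has columns time, event, signature_z and one
    column per configured covariate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sig = list(config.signature)
    if config.gene_universe:
        missing = set(sig) - set(config.gene_universe)
        if missing:
            raise InvalidConfigError(f"signature genes outside universe: {sorted(missing)[:5]}")
        gene_ids = pd.Index(sorted(set(config.gene_universe)))
    else:
        gene_ids = pd.Index(
            sorted(set(sig) | {f"B{i:05d}" for i in range(config.n_genes - len(sig))})
        )

    z = rng.normal(size=n)
    base = rng.normal(3.0, 1.0, (len(gene_ids), 1)) + rng.normal(0.0, 0.5, (len(gene_ids), n))
    sig_rows = gene_ids.get_indexer(sig)
    base[sig_rows, :] += config.enrichment_effect * z[None, :]
    expression = pd.DataFrame(
        np.expm1(np.clip(base, None, 20.0)).clip(min=0.0),
        index=gene_ids,
        columns=[f"S{i:04d}" for i in range(n)],
    )

    log_hr = np.log(config.hazard_ratio_per_sd) * z
    cov_data = {}
    for name, effect in config.covariates:
        x = rng.normal(size=n)
        cov_data[name] = x
        log_hr = log_hr + effect * x
    hazard = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)

    event = np.ones(n, dtype=int)
    time = event_time.copy()
    censored = rng.random(n) < config.censor_rate
    ct = rng.uniform(0.0, event_time)
    time[censored] = ct[censored]
    event[censored] = 0

    survival = pd.DataFrame(
        {"time": time, "event": event, "signature_z": z, **cov_data},
        index=expression.columns,
    )
    survival.index.name = "sample_id"
    return expression, survival


def generate_trait_lists(
    n_traits: int,
    overlap_with: dict,
    overlap_frac: float,
    seed: int,
    list_size: int = 1000,
    universe: list | None = None,
    target_set: str | None = None,
) -> dict:
    """Emit trait gene tables with controlled overlap against a target set.

    Each trait list holds ``round(overlap_frac * list_size)`` genes drawn
    from the designated target set and the remainder drawn uniformly from
    the background universe, mimicking GWAS-derived ranked gene lists.
    """
    if not 0.0 <= overlap_frac <= 1.0:
        raise InvalidConfigError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if target_set is None:
        target_set = next(iter(overlap_with))
    target = list(dict.fromkeys(overlap_with[target_set]))
    if universe is None:
        pool = sorted({g for genes in overlap_with.values() for g in genes})
        universe = pool + [f"U{i:05d}" for i in range(max(0, 5 * list_size - len(pool)))]
    universe = list(dict.fromkeys(universe))

    n_target = min(int(round(overlap_frac * list_size)), len(target))
    traits = {}
    for t in range(n_traits):
        chosen = list(rng.choice(target, size=n_target, replace=False)) if n_target else []
        # remainder drawn uniformly from the whole universe minus what is
        # already in the list, so chance overlap with the target remains
        remainder_pool = [g for g in universe if g not in set(chosen)]
        n_bg = min(list_size - n_target, len(remainder_pool))
        chosen += list(rng.choice(remainder_pool, size=n_bg, replace=False))
        score = np.linspace(1.0, 0.0, len(chosen), endpoint=False)
        traits[f"trait_{t:03d}"] = pd.DataFrame({"gene": chosen, "score": score})
    return traits


__all__ = [
    "BulkSimConfig",
    "SimConfig",
    "SyntheticCohort",
    "generate_bulk_survival",
    "generate_cohort",
    "generate_trait_lists",
]
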