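import numpy as np
import pytest

from fibrotype import qc
from fibrotype.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def planted3():
    """3-subtype cohort with strong planted markers, normalized."""
    cfg = SimConfig(
        n_genes=2000, n_cells=3000, n_subtypes=3, markers_per_subtype=50,
        marker_log2fc=2.0, seed=1,
    )
    syn = generate_cohort(cfg)
    syn.cohort = qc.normalize_log(syn.cohort)
    return syn


@pytest.fixture(scope="session")
def planted2_small():
    """2-subtype cohort, single batch, used by purity/DEG/merge tests."""
    cfg = SimConfig(
        n_genes=1200, n_cells=1200, n_subtypes=2, markers_per_subtype=80,
        marker_log2fc=2.0, n_batches=1, seed=1,
    )
    syn = generate_cohort(cfg)
    syn.cohort = qc.normalize_log(syn.cohort)
    return syn


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
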