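import numpy as np
import pandas as pd
import pytest

from txpod.pipeline import RunConfig, analyze_study
from txpod.simulate import SimConfig, simulate_study

DOSES = np.array([0.0, 2.5, 5.0, 10.0, 25.0, 75.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    cfg = SimConfig(
        n_genes=300,
        frac_responsive=0.3,
        n_pathways=16,
        pathway_size=12,
        enrichment_frac=0.8,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_result(small_study):
    """Full analysis of the small study (no bootstrap), shared read-only."""
    cfg = RunConfig(n_permutations=200, seed=7)
    return analyze_study(
        small_study.expression,
        small_study.doses,
        small_study.pathways,
        small_study.regulators,
        config=cfg,
        run_bootstrap=False,
    )


def make_gene_table(bmds, bmdls=None, genes=None):
    """Helper: a post-filtered gene BMD table from raw numbers."""
    bmds = np.asarray(bmds, float)
    if genes is None:
        genes = [f"g{i}" for i in range(len(bmds))]
    if bmdls is None:
        bmdls = bmds / 2.0
    return pd.DataFrame(
        {"gene": genes, "family": "linear", "bmd": bmds, "bmdl": bmdls,
         "gof_p": 0.5}
    )
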