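import numpy as np
import pandas as pd
import pytest

from eqtm.core import AnalysisConfig, OmicsMatrix, SampleSheet
from eqtm.preprocess import beta_to_m
from eqtm.synthetic import CpGSpec, GeneSpec, SyntheticConfig, generate_cohort
from eqtm.table1 import table1_fixture


@pytest.fixture(scope="session")
def table1():
    annotations, records = table1_fixture()
    return annotations, records


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_cohort(genes, seed=0, n1=14, n2=10, effects=None, noise_sd=0.5):
    """Small synthetic cohort without the default covariate noise unless
    effects are requested."""
    cfg = SyntheticConfig(
        genes=genes,
        n_group1=n1,
        n_group2=n2,
        covariate_effects=effects or {},
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_cohort(cfg)


def as_mvalues(beta: OmicsMatrix) -> OmicsMatrix:
    m = OmicsMatrix("mvalue", beta.data.copy())
    m.data.iloc[:, :] = beta_to_m(beta.data.to_numpy(dtype=float))
    return m


@pytest.fixture
def small_cohort():
    """One correlated gene (3 CpGs), one null gene; 14 + 10 samples."""
    genes = [
        GeneSpec(
            "GENEA",
            cpgs=(
                CpGSpec("cgA1", rho_group1=0.8, rho_group2=0.8),
                CpGSpec("cgA2", feature="TSS200", rho_group1=-0.8, rho_group2=-0.8),
                CpGSpec("cgA3", rho_group1=0.0, rho_group2=0.0),
            ),
        ),
        GeneSpec("GENEB", cpgs=(CpGSpec("cgB1"), CpGSpec("cgB2"))),
    ]
    beta, expr, sheet, annotations, truth = make_cohort(genes, seed=5)
    return as_mvalues(beta), expr, sheet, annotations, truth


@pytest.fixture
def default_config():
    return AnalysisConfig()
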