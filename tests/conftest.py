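import numpy as np
import pytest
from hypothesis import settings

from abt import PolygenicModel, SimConfig, partition_by_gene, simulate_study
from abt.simulate import DESIGN_COLUMNS, design_matrix

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A compact but fully structured study: trios + couples + singletons."""
    cfg = SimConfig(n_families=40, n_unrelated=20, n_genes=30,
                    snps_per_gene=(1, 10), seed=7)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_fit(small_study):
    Z = design_matrix(small_study.covariates)
    model = PolygenicModel(small_study.phenotype, Z, small_study.kinship,
                           exog_names=DESIGN_COLUMNS)
    return model.fit()


@pytest.fixture(scope="session")
def small_partitions(small_study):
    return partition_by_gene(small_study.genotypes, small_study.gene_regions)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
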