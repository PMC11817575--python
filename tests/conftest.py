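import numpy as np
import pytest

from molsubtype.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for mechanics tests (not the default study conditions)."""
    cfg = CohortConfig(n_clusters=3, samples_per_cluster=10, n_genes=300,
                       n_gene_sets=40, set_size_min=8, set_size_max=15,
                       pathways_per_cluster=4, effect_size=2.0,
                       n_reversers_per_cluster=5, n_decoy_drugs=60,
                       n_decoy_targets=30, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (4 planted clusters, 30 samples each)."""
    return generate_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
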