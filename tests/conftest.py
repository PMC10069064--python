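import numpy as np
import pytest

from oscmeta.simulate import CohortSpec, default_profile, gen_expression_cohorts


@pytest.fixture(scope="session")
def default_cohorts():
    """The default 18-cohort simulation profile (true target SMD 0.9)."""
    specs = default_profile(seed=11)
    return gen_expression_cohorts(specs)


@pytest.fixture()
def small_cohort():
    """One small cohort: 10/10 samples, 50 genes, target SMD 1.2."""
    spec = CohortSpec(
        dataset_id="DS1", platform_id="P1", n_tumor=10, n_normal=10,
        n_genes=50, target_effect=1.2, block_genes=10, block_loading=0.8,
        seed=7,
    )
    datasets, truth = gen_expression_cohorts([spec])
    return datasets[0], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
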