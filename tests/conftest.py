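import numpy as np
import pytest

from p53sig import cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted cohort: 30 sensitive vs 60 insensitive, 300 genes
    (13 signature + background), fixed seed."""
    cfg = cohort.GeneratorConfig(n_sensitive=30, n_insensitive=60,
                                 n_genes=300, seed=11)
    return cohort.generate_cohort(cfg, pdx=True)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return small_cohort.annotation["true_class"]


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every fold change at 1.0: no signal anywhere."""
    fcs = {g: 1.0 for g in cohort.SIGNATURE_FOLD_CHANGES}
    cfg = cohort.GeneratorConfig(n_sensitive=30, n_insensitive=60,
                                 n_genes=300, seed=13,
                                 signature_fold_changes=fcs)
    return cohort.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
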