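import numpy as np
import pytest

from mireqtl.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_small():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_individuals=150, n_snps=8, n_mirnas=40, seed=11, pi_zero=0.1
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
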