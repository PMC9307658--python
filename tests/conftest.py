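import numpy as np
import pytest

from myelinpath import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort used by several preprocessing tests."""
    cfg = GeneratorConfig(n_subjects=12, n_voxels=40, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231114)
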