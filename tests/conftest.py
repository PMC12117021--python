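import numpy as np
import pytest

from neglectdisc import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg() -> sd.SynthConfig:
    """Desk-scale study conditions reused across tests."""
    return sd.SynthConfig(seed=11, n_subjects=3, n_timepoints=50, n_patients=20)


@pytest.fixture(scope="session")
def anatomy(small_cfg):
    return sd.make_anatomy(small_cfg)


@pytest.fixture(scope="session")
def cohort(small_cfg, anatomy):
    return sd.make_cohort(small_cfg, anatomy)


@pytest.fixture(scope="session")
def connectome(small_cfg, anatomy):
    return sd.make_connectome(small_cfg, anatomy)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
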