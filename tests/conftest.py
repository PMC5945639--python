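import numpy as np
import pytest

from ripuse import MIR100_5P, MIR125B_5P, SyntheticConfig, generate


@pytest.fixture(scope="session")
def mir100():
    return MIR100_5P


@pytest.fixture(scope="session")
def mir125b():
    return MIR125B_5P


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted experiment shared by several module tests."""
    cfg = SyntheticConfig(seed=11, n_transcripts=400, utr_length=(300, 500))
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (2,000 transcripts, seed 1)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
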