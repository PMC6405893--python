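import numpy as np
import pytest

from tigerpop import synthetic as syn


@pytest.fixture(scope="session")
def clean_config():
    """Error-free generator settings: replicates must equal the truth."""
    return syn.SyntheticConfig(
        seed=11, dropout_rate=0.0, false_allele_rate=0.0, missing_rate=0.0
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return syn.simulate_dataset(clean_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small on-disk synthetic fixture shared across pipeline tests."""
    cfg = syn.SyntheticConfig(seed=42)
    truth, reps, sexm, occ = syn.simulate_dataset(cfg)
    d = tmp_path_factory.mktemp("fixture")
    syn.write_fixture(truth, reps, occ, d, sexm)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
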