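import numpy as np
import pytest

from mstscan import make_fixture_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240625)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Small synthetic bed/bim/fam + pheno/covar set shared across tests."""
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture_dataset(out, n=400, n_snps=40, k=3, seed=7,
                                missing_rate=0.02)
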