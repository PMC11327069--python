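import numpy as np
import pytest

from epilnc import synthetic_data as sd


@pytest.fixture(scope="session")
def cohort():
    """Default study-condition cohort (300 genes, 20/20 samples, seed 1)."""
    return sd.simulate_cohort(sd.SimConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    sd.write_bundles(cohort, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
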