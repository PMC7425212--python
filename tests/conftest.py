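import pytest

from alomine.orffinder import MinerConfig
from alomine.tprscan import calibrate_null, load_builtin_profile


@pytest.fixture(scope="session")
def profile():
    return load_builtin_profile()


@pytest.fixture(scope="session")
def calibration(profile):
    return calibrate_null(profile, n_shuffles=120, seed=0)


@pytest.fixture()
def miner_config():
    return MinerConfig()
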