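import numpy as np
import pytest

import cropwue as cw


@pytest.fixture(scope="session")
def zone_table():
    return cw.default_zone_table()


@pytest.fixture(scope="session")
def default_params(zone_table):
    """The worldwide-pooled ('Default') calibrated parameter triple."""
    return zone_table.default_entry


@pytest.fixture()
def params():
    """A round-number parameter set for hand-checkable examples."""
    return cw.LUEParameters(eps_max=3.0, t_opt=30.0, vpd0=2.0)


@pytest.fixture(scope="session")
def small_config():
    return cw.SyntheticConfig(n_sites=3, n_years=1, seed=7, noise_sd_frac=0.05)


@pytest.fixture(scope="session")
def site_forcing(small_config):
    """One synthetic site-year of daily forcing (DataFrame)."""
    return cw.generate_daily_forcing(small_config)["site00"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
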