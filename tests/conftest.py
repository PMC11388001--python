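import logging

import pytest

import urbanheat as uh

# silence the UTCI domain-clamp warnings that fire on calm synthetic winds
logging.getLogger("urbanheat.comfort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_grid() -> uh.UrbanGrid:
    return uh.gen_urban_grid(200, seed=11)


@pytest.fixture(scope="session")
def heatwave_met(small_grid) -> uh.MetField:
    return uh.gen_met_forcing(small_grid, n_days=2, seed=12)
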