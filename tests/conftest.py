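import numpy as np
import pytest
from hypothesis import settings

import soilghg as sg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    ps = sg.default_parameters()
    ps.validate()
    return ps


@pytest.fixture(scope="session")
def world_spec():
    return sg.SyntheticSpec(seed=20, nlat=20, nlon=40, n_years=5)


@pytest.fixture(scope="session")
def world(world_spec):
    """Climate + soil + CH4 series for the default synthetic planet."""
    climate = sg.synth_climate(world_spec)
    soil = sg.synth_soil(world_spec)
    ch4 = sg.synth_ch4_series(world_spec)
    return climate, soil, ch4


@pytest.fixture(scope="session")
def flux_field(world, params):
    climate, soil, ch4 = world
    return sg.run_grid(climate, soil, params, ch4)


@pytest.fixture(scope="session")
def loam():
    return sg.SoilPhysiochem(cnr=15.0, bd=1.3, sand_pct=40.0, clay_pct=20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
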