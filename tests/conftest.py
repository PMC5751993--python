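import numpy as np
import pytest

from camtrap.data import Station
from camtrap.simulate import DEFAULT_SPECIES, SimScenario, sim_stations


@pytest.fixture()
def rng():
    return np.random.default_rng(20180103)


@pytest.fixture(scope="session")
def scenario():
    """Four-site study-design scenario."""
    return SimScenario(seed=20180103)


@pytest.fixture(scope="session")
def stations(scenario):
    return sim_stations(scenario)


@pytest.fixture(scope="session")
def wlp_scenario():
    """Single-species scenario (white-lipped peccary truth)."""
    return SimScenario(seed=20180103, species=(DEFAULT_SPECIES[0],))


def make_station(station_id="S1", site="A", x=0.0, y=0.0, n_days=90, **kw):
    defaults = dict(
        dist_road=10.0, dist_river=2.0, dist_settlement=5.0,
        habitat=0, cam_spacing=6.0, active=np.ones(n_days, dtype=bool),
    )
    defaults.update(kw)
    return Station(station_id=station_id, site=site, x=x, y=y, **defaults)


@pytest.fixture()
def tiny_stations():
    return [
        make_station("S1", x=0.0, y=0.0),
        make_station("S2", x=3.0, y=4.0),
        make_station("S3", x=6.0, y=0.0, habitat=1),
    ]
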