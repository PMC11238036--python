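import numpy as np
import pytest

from riversdm import streams as st
from riversdm import synthetic as syn
from riversdm.grids import ElevationGrid


@pytest.fixture(scope="session")
def world_config():
    return syn.SyntheticWorldConfig(seed=7)


@pytest.fixture(scope="session")
def dem(world_config):
    return syn.make_dem(world_config)


@pytest.fixture(scope="session")
def climate(dem, world_config):
    fine, coarse, stations = syn.make_monthly_climate(dem, world_config)
    return fine, coarse, stations


@pytest.fixture(scope="session")
def network_bundle(dem):
    """filled DEM, flow grid, stream mask and characterized network."""
    filled = st.fill_sinks(dem)
    flow = st.flow_accumulation(st.flow_direction(filled))
    mask = st.extract_streams(flow, 0.1)
    net = st.segment_reaches(mask, flow, 100.0)
    st.characterize_network(net, filled, flow)
    return filled, flow, mask, net


def tilted_plane(rows=12, cols=12, cell=100.0, slope=0.01, axis="x"):
    """Pitless plane rising along +x (east) or +y (north)."""
    if axis == "x":
        vals = slope * cell * (np.arange(cols) + 0.5)
        vals = np.broadcast_to(vals, (rows, cols)).copy()
    else:
        vals = slope * cell * (np.arange(rows) + 0.5)[::-1]
        vals = np.broadcast_to(vals[:, None], (rows, cols)).copy()
    return ElevationGrid(values=vals, cell_size=cell)


@pytest.fixture
def plane():
    return tilted_plane()
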