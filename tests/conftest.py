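import logging

import numpy as np
import pytest

from densecon.assembly import build_network
from densecon.fixtures import (
    FixtureConfig,
    make_ground_truth_network,
    make_input_bundle,
    make_meta,
)
from densecon.reference_frame import (
    Column,
    LaminarZone,
    ReferenceFrame,
    VoxelGrid,
)

# clip warnings about morphology pieces leaving the toy grid are expected
logging.getLogger("densecon.density_fields").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ground_truth():
    """Six directly placed neurons with a dense brute-force oracle."""
    return make_ground_truth_network(n_neurons=6, seed=1)


@pytest.fixture(scope="session")
def toy_cfg():
    return FixtureConfig(dims=(8, 8, 4))


@pytest.fixture(scope="session")
def toy_bundle(toy_cfg):
    return make_input_bundle(toy_cfg)


@pytest.fixture(scope="session")
def toy_meta(toy_cfg):
    return make_meta(toy_cfg)


@pytest.fixture(scope="session")
def toy_network(toy_bundle):
    return build_network(toy_bundle, seed=3)


@pytest.fixture()
def simple_frame():
    """Two parallel columns along x, three named zones each."""
    grid = VoxelGrid(origin=np.zeros(3), spacing=50.0, dims=(8, 8, 8))
    columns = [
        Column(id="A", center=np.array([100.0, 200.0, 200.0]),
               axis=np.array([0.0, 0.0, 1.0]), radius=90.0,
               top_depth=-200.0, bottom_depth=200.0),
        Column(id="B", center=np.array([300.0, 200.0, 200.0]),
               axis=np.array([0.0, 0.0, 1.0]), radius=90.0,
               top_depth=-200.0, bottom_depth=200.0),
    ]
    zones = []
    for cid in ("A", "B"):
        zones.extend([
            LaminarZone(cid, "supragranular", 0.0, 100.0),
            LaminarZone(cid, "granular", 100.0, 200.0),
            LaminarZone(cid, "infragranular", 200.0, 400.0),
        ])
    return ReferenceFrame(grid, columns, zones)
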