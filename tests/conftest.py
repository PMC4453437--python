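import numpy as np
import pytest

from grid3d.analysis3d import autocorr3d
from grid3d.config import RunConfig, SimConfig
from grid3d.fixtures import make_fixture


@pytest.fixture(scope="session")
def fcc_map():
    return make_fixture("fcc", a=0.3, resolution=48, n=4)


@pytest.fixture(scope="session")
def hcp_map():
    return make_fixture("hcp", a=0.3, resolution=48, n=4)


@pytest.fixture(scope="session")
def fcc_ac(fcc_map):
    return autocorr3d(fcc_map)


@pytest.fixture(scope="session")
def hcp_ac(hcp_map):
    return autocorr3d(hcp_map)


@pytest.fixture(scope="session")
def reduced_run():
    """One shared reduced-scale learning run (27 units, 8^3 inputs, 1M steps)."""
    from grid3d.simulator import run

    sim = SimConfig(n_mec=27, per_axis_inp=8, seed=1)
    cfg = RunConfig(
        sim=sim,
        n_steps=1_000_000,
        checkpoints=(250_000, 500_000, 750_000, 1_000_000),
        map_shape=(25, 25, 25),
    )
    return run(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
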