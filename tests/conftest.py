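import numpy as np
import pytest

from tcpalm import (
    AcquisitionParams,
    PhotophysicsParams,
    ClusterSpec,
    live_cluster_specs,
    simulate_live_cell,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def phot():
    return PhotophysicsParams()


@pytest.fixture(scope="session")
def live_table(acq, phot):
    """Default live-cell preset (10 clusters, 50 Hz background), seed 0."""
    specs = live_cluster_specs(acq, seed=0)
    return simulate_live_cell(acq, phot, specs, background_rate_hz=50.0, seed=0), specs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def single_cluster_spec(acq):
    return ClusterSpec(
        center_xy_nm=(5000.0, 5000.0),
        radius_nm=60.0,
        t_on_s=20.0,
        lifetime_s=8.0,
        n_molecules=80,
    )
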