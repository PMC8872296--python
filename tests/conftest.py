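import numpy as np
import pytest

from metroexposure import build_default_station, pipeline, rasterize
from metroexposure.pedestrians import DemandSpec, simulate_trajectories


@pytest.fixture(scope="session")
def geometry():
    return build_default_station()


@pytest.fixture(scope="session")
def grids(geometry):
    return rasterize(geometry, 0.4)


@pytest.fixture(scope="session")
def short_sim(geometry):
    """A 600-s simulation: enough agents for distributional checks."""
    return simulate_trajectories(DemandSpec(), geometry, duration=600.0,
                                 seed=123)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The default synthetic study (default RunConfig, artifacts written)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.RunConfig(outdir=str(outdir))
    return pipeline.run_full(cfg)


@pytest.fixture(scope="session")
def noiseless_run():
    """Default study at zero instrument noise (recovery ceiling check)."""
    return pipeline.run_full(pipeline.RunConfig(noise_sd=0.0), write=False)
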