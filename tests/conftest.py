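import numpy as np
import pytest

from nanoftir.config import RunConfig
from nanoftir.interferometry import default_bands, default_simulation_grid
from nanoftir.pipeline import run_pipeline
from nanoftir.scene import make_blend_scene, make_hair_scene


@pytest.fixture(scope="session")
def sim_grid():
    return default_simulation_grid()


@pytest.fixture(scope="session")
def bands(sim_grid):
    return default_bands(sim_grid)


@pytest.fixture(scope="session")
def blend_scene():
    return make_blend_scene(seed=0)


@pytest.fixture(scope="session")
def hair_scene():
    return make_hair_scene(seed=0)


@pytest.fixture(scope="session")
def noiseless_run():
    """Seed-0 blend pipeline: no noise, no drifts."""
    cfg = RunConfig(seed=0, noise_sd=0.0, path_drift_cm=(0.0, 0.0, 0.0))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def noisy_run():
    """Seed-0 blend pipeline with default noise and per-band path drifts."""
    return run_pipeline(RunConfig(seed=0))


@pytest.fixture(scope="session")
def driftfree_noisy_run():
    """Seed-0 blend pipeline with default noise but no interferometer drift."""
    return run_pipeline(RunConfig(seed=0, path_drift_cm=(0.0, 0.0, 0.0)))


@pytest.fixture(scope="session")
def analysis_mask(blend_scene):
    """Pixels analysed downstream: everything except the reference strip."""
    mask = np.ones(blend_scene.shape, dtype=bool)
    mask[blend_scene.labels == 0] = False
    return mask
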