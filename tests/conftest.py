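import numpy as np
import pytest

from brixvis import synthetic_data as sd
from brixvis.scanproc import BackgroundSpectrum, MultiPointScan, WavelengthGrid


@pytest.fixture(scope="session")
def small_grid():
    return WavelengthGrid(np.linspace(560.0, 1072.0, 101))


@pytest.fixture(scope="session")
def small_config(small_grid):
    """Cheap 101-channel simulation config for unit tests."""
    return sd.SimulationConfig(seed=0, grid=small_grid)


@pytest.fixture(scope="session")
def quiet_config(small_grid):
    """Deterministic forward model: no noise, no scatter, no saturation."""
    return sd.SimulationConfig(
        seed=0,
        grid=small_grid,
        noise_sd=0.0,
        background_noise_sd=0.0,
        scatter_gain_range=(1.0, 1.0),
        saturation_prob=0.0,
        band_jitter_sd=0.0,
        interferent_bands=(),
    )


@pytest.fixture(scope="session")
def tiny_profile():
    return sd.VarietyProfile("tiny", 3.8, 8.7, 5.8, 1.1, 8, points_min=5, points_max=9)


def make_scan(points, grid=None, sample_id="t", orientation="O1"):
    points = np.asarray(points, dtype=float)
    if grid is None:
        grid = WavelengthGrid(np.linspace(560.0, 1072.0, points.shape[1]))
    return MultiPointScan(sample_id=sample_id, orientation=orientation,
                          points=points, grid=grid)


def make_background(p, level=0.0, noise_sd=1.0):
    return BackgroundSpectrum(intensity=np.full(p, float(level)), noise_sd=noise_sd)
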