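import numpy as np
import pytest

from driftwood.raster import GridSpec, MultibandRaster
from driftwood.synthetic_scene import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def small_truth():
    """A 768 m tile at 3 m with a handful of deposits; shared read-only."""
    cfg = LandscapeConfig(
        extent_m=(768.0, 768.0),
        pixel_size_m=3.0,
        n_years=3,
        n_scenes_per_year=2,
        river_mouths=[(384.0, True)],
        n_deposits_per_mouth=12,
        remobilization_prob=0.25,
        log_fraction=0.25,
        seed=42,
    )
    return generate_landscape(cfg)


@pytest.fixture
def unit_grid():
    """10x10 grid of 3 m pixels with origin (0, 30)."""
    return GridSpec(x0=0.0, y0=30.0, px=3.0, py=3.0, rows=10, cols=10)


def raster_from(array, px=3.0, nodata=-9999.0):
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    grid = GridSpec(x0=0.0, y0=arr.shape[1] * px, px=px, py=px,
                    rows=arr.shape[1], cols=arr.shape[2])
    return MultibandRaster(data=arr, grid=grid, nodata=nodata)


@pytest.fixture
def make_raster():
    return raster_from
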