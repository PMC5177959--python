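import numpy as np
import pytest

from aeoscan.raster_core import BandStack, GridGeometry
from aeoscan.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """Compact synthetic scene shared by read-only tests."""
    return generate_scene(SceneSpec(n_rows=30, n_cols=30, seed=7))


@pytest.fixture
def square_geometry():
    def make(n_rows, n_cols, cell=100.0):
        return GridGeometry(
            origin_x=0.0,
            origin_y=n_rows * cell,
            cell_size_x=cell,
            cell_size_y=cell,
            n_rows=n_rows,
            n_cols=n_cols,
        )

    return make


@pytest.fixture
def make_stack(square_geometry):
    def make(bands, cell=100.0, mask=None, labels=None):
        bands = np.asarray(bands, dtype=float)
        if bands.ndim == 2:
            bands = bands[None]
        geom = square_geometry(bands.shape[1], bands.shape[2], cell)
        labels = labels or [f"band{i + 1}" for i in range(bands.shape[0])]
        return BandStack(geometry=geom, bands=bands, band_labels=labels, nodata_mask=mask)

    return make
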