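import numpy as np
import pytest

from adaptscape import Grid, LandscapeParams, generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_landscape():
    """32x32 landscape with PAs, relief and hydrography; fast for unit tests."""
    return generate_landscape(LandscapeParams(n_rows=32, n_cols=32, n_pas=5,
                                              hydro_threshold=8, seed=11))


@pytest.fixture(scope="session")
def study_landscape():
    """128x128 landscape at the study defaults (14% PA cover, 95-yr horizon)."""
    return generate_landscape(LandscapeParams(seed=5))


def random_grid(rng, nr, nc, cell_km=1.0, lat_top=44.0, nodata_frac=0.0):
    values = rng.normal(50.0, 20.0, (nr, nc))
    nodata = rng.random((nr, nc)) < nodata_frac
    lats = lat_top - 0.01 * np.arange(nr)
    return Grid(values, nodata=nodata, cell_km=cell_km, row_latitudes=lats)
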