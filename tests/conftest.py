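import numpy as np
import pytest

import orchidsdm as o


@pytest.fixture(scope="session")
def small_grid() -> o.GridSpec:
    return o.GridSpec(
        origin_x=0.0, origin_y=10_000.0, n_rows=10, n_cols=10,
        cell_size=1000.0, crs_id="synthetic-equal-area",
    )


@pytest.fixture(scope="session")
def landscape() -> o.Landscape:
    """A 60x60 synthetic study system shared by read-only tests."""
    params = o.LandscapeParams(
        seed=11,
        grid=o.GridSpec(0.0, 60_000.0, 60, 60, crs_id="synthetic-equal-area"),
        n_counties=10,
    )
    return o.generate_landscape(params)


@pytest.fixture(scope="session")
def hi_raster(landscape) -> o.Raster:
    return o.compute_hi(landscape)


@pytest.fixture(scope="session")
def stack(landscape, hi_raster) -> o.PredictorStack:
    return o.assemble_stack(landscape, hi_raster)


def make_raster(grid: o.GridSpec, values, mask=None, categorical=False) -> o.Raster:
    return o.Raster(grid, np.asarray(values), mask, categorical)
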