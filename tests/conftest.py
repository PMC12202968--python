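"""Shared fixtures: one coarse synthetic world reused across the suite.

Everything is generated at test time from seeded truth parameters; the grid
is deliberately coarse (50-km equal-area cells over the eastern US) so the
whole suite runs in minutes.
"""

import numpy as np
import pytest

from isomove import (
    AlbersEqualArea,
    Isoscape,
    PipelineConfig,
    SyntheticTruth,
    make_isoscape,
    make_known_origin_samples,
    reproject_to_albers,
)
from isomove.synthetic import make_county_centroids


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def albers():
    return AlbersEqualArea()


@pytest.fixture(scope="session")
def iso_albers(truth, albers):
    iso_geo = make_isoscape(truth.extent, 0.5, truth)
    return Isoscape(reproject_to_albers(iso_geo.grid, albers, 50.0))


@pytest.fixture(scope="session")
def centroids(truth):
    return make_county_centroids(truth)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(random_seed=5)


@pytest.fixture(scope="session")
def known200(iso_albers, truth):
    summer = truth.season_polygons["spring_summer"]
    return make_known_origin_samples(iso_albers, truth, 200, seed=11, within=summer)


def make_row_surface(mu_values, y, sigma, sample_id="s"):
    """1×N equal-area grid surface helper for hand-computable examples."""
    from isomove.assignment import assignment_surface
    from isomove.calibration import FurSample
    from isomove.geodesy import GeoPoint
    from isomove.raster import RasterGrid
    import datetime

    mu_values = np.asarray(mu_values, dtype=float).reshape(1, -1)
    grid = RasterGrid(
        mu_values,
        np.zeros_like(mu_values, dtype=bool),
        (0.0, 10.0, 10.0, -10.0),
        AlbersEqualArea().crs,
    )
    sample = FurSample(sample_id, y, GeoPoint(-96.0, 23.0), datetime.date(2020, 9, 1))
    return assignment_surface(sample, grid, sigma, mask=None)
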