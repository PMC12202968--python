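"""Origin surfaces, quantile transform, threshold calibration, overlays."""

import datetime

import numpy as np
import pytest

from isomove import (
    assignment_surface,
    build_range_mask,
    calibrate_threshold,
    cumulative_origin_proportion,
    likely_region,
    quantile_transform,
)
from isomove.alphahull import InsufficientPointsError
from isomove.assignment import NoDomainError, QuantileSurface
from isomove.calibration import FurSample
from isomove.geodesy import GeoPoint, destination
from isomove.projection import AlbersEqualArea
from isomove.raster import RasterGrid

from conftest import make_row_surface

DATE = datetime.date(2020, 9, 1)


# ------------------------------------------------------------------ range mask
def test_triangle_mask_contains_and_buffers(albers):
    pts = [GeoPoint(-90.0, 30.0), GeoPoint(-85.0, 35.0), GeoPoint(-92.0, 36.0)]
    mask = build_range_mask(pts, albers, alpha_km=100.0, buffer_km=250.0)
    import shapely

    xy = np.array([albers.forward(p.lon, p.lat) for p in pts])
    assert shapely.covers(mask.polygon, shapely.points(xy)).all()
    # a point 240 km outside the (convex) hull is still inside the 250-km buffer
    hull = shapely.MultiPoint(xy).convex_hull
    outside_lon, outside_lat = destination(-85.0, 35.0, 90.0, 240_000.0)
    ox, oy = albers.forward(float(outside_lon), float(outside_lat))
    assert not hull.covers(shapely.Point(ox, oy))
    assert mask.polygon.covers(shapely.Point(ox, oy))


def test_zero_buffer_infinite_alpha_is_convex_hull(albers):
    import shapely

    pts = [GeoPoint(-90, 30), GeoPoint(-85, 35), GeoPoint(-92, 36), GeoPoint(-88, 31)]
    mask = build_range_mask(pts, albers, alpha_km=np.inf, buffer_km=0.0)
    xy = np.array([albers.forward(p.lon, p.lat) for p in pts])
    hull = shapely.MultiPoint(xy).convex_hull
    assert mask.polygon.symmetric_difference(hull).area < 1e-9


def test_mask_needs_three_points(albers):
    with pytest.raises(InsufficientPointsError):
        build_range_mask([GeoPoint(-90, 30), GeoPoint(-85, 35)], albers)


# ---------------------------------------------------------------- surfaces
def test_symmetric_two_cell_split():
    s = make_row_surface([-35.0, -25.0], y=-30.0, sigma=8.0)
    np.testing.assert_allclose(s.grid.values[0], [0.5, 0.5])


def test_three_cell_hand_computed_normal_densities():
    # mu = (-20, -40, -60), sigma = 10, y = -30: densities e^-0.5, e^-0.5, e^-4.5
    s = make_row_surface([-20.0, -40.0, -60.0], y=-30.0, sigma=10.0)
    np.testing.assert_allclose(s.grid.values[0], [0.495463, 0.495463, 0.009074], atol=5e-6)


def test_single_cell_is_certain():
    s = make_row_surface([-50.0], y=-120.0, sigma=5.0)
    assert s.grid.values[0, 0] == 1.0


def test_sigma_must_be_positive():
    with pytest.raises(ValueError):
        make_row_surface([-50.0, -60.0], y=-55.0, sigma=0.0)


def test_empty_domain_raises(albers):
    grid = RasterGrid(np.zeros((2, 2)), np.ones((2, 2), bool), (0, 100, 50.0, -50.0), albers.crs)
    sample = FurSample("x", -60.0, GeoPoint(-96, 23), DATE)
    with pytest.raises(NoDomainError):
        assignment_surface(sample, grid, 10.0)


def test_mass_conservation_and_sigma_concentration():
    rng = np.random.default_rng(0)
    mu = rng.normal(-60, 12, 400)
    best = None
    for sigma in (20.0, 10.0, 5.0, 2.0):
        s = make_row_surface(mu, y=-52.0, sigma=sigma)
        p = s.grid.values[~s.grid.nodata_mask]
        assert abs(p.sum() - 1.0) < 1e-9
        top = p.max()
        if best is not None:
            assert top >= best  # shrinking sigma concentrates mass
        best = top


def test_surface_far_from_all_cells_does_not_underflow():
    s = make_row_surface([-250.0, -260.0], y=40.0, sigma=2.0)
    assert abs(s.grid.values.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------- quantiles
def test_quantile_examples():
    s = make_row_surface([-20.0, -40.0, -60.0, -80.0], y=-20.0, sigma=10.0)
    # probabilities strictly decreasing -> quantiles are the ECDF ranks
    q = quantile_transform(s)
    np.testing.assert_allclose(np.sort(q.grid.values[0]), [0.25, 0.5, 0.75, 1.0])
    assert q.grid.values[0, np.argmax(s.grid.values[0])] == 1.0


def test_uniform_surface_maps_to_all_ones():
    s = make_row_surface([-50.0] * 6, y=-55.0, sigma=10.0)
    q = quantile_transform(s)
    np.testing.assert_array_equal(q.grid.values[0], np.ones(6))


# ------------------------------------------------------------- calibration
def _quantile_surface_from(values, albers):
    vals = np.asarray(values, dtype=float).reshape(1, -1)
    grid = RasterGrid(vals, np.zeros_like(vals, bool), (0.0, 10.0, 10.0, -10.0), albers.crs)
    return QuantileSurface(grid, "t")


def _sample_at_cell(i, albers):
    lon, lat = albers.inverse(10.0 * i + 5.0, 5.0)
    return FurSample(f"t{i}", -60.0, GeoPoint(float(lon), float(lat)), DATE,
                     GeoPoint(float(lon), float(lat)))


def test_threshold_enumeration_worked_example(albers):
    # true-origin quantiles {0.2, 0.4, 0.6, 0.8}: 3/4 are >= 0.4
    samples = [_sample_at_cell(0, albers) for _ in range(4)]
    surfaces = [
        _quantile_surface_from([q, 1.0, 1.0, 1.0], albers) for q in (0.2, 0.4, 0.6, 0.8)
    ]
    theta = calibrate_threshold(samples, surfaces, target_accuracy=0.75)
    assert theta == pytest.approx(0.4)
    # target 1.0 must cover every sample: theta = min of the quantiles
    assert calibrate_threshold(samples, surfaces, target_accuracy=1.0) == pytest.approx(0.2)


def test_threshold_all_perfect_is_one(albers):
    samples = [_sample_at_cell(0, albers)]
    surfaces = [_quantile_surface_from([1.0, 0.4, 0.2, 0.1], albers)]
    assert calibrate_threshold(samples, surfaces, 0.75) == 1.0


def test_threshold_requires_test_set(albers):
    with pytest.raises(ValueError):
        calibrate_threshold([], [], 0.75)


# ------------------------------------------------------------ likely regions
def test_likely_region_examples():
    s = make_row_surface([-20.0, -40.0, -60.0, -80.0], y=-20.0, sigma=10.0)
    q = quantile_transform(s)
    r = likely_region(q, 0.6)
    assert r.mask.sum() == 2  # the two highest-probability cells
    assert likely_region(q, 1.0).mask.sum() == 1  # argmax only
    min_q = q.grid.values[~q.grid.nodata_mask].min()
    assert likely_region(q, min_q).mask.sum() == 4  # whole domain
    with pytest.raises(ValueError):
        likely_region(q, 0.0)


def test_cumulative_overlay():
    s = make_row_surface([-20.0, -40.0, -60.0, -80.0], y=-20.0, sigma=10.0)
    q = quantile_transform(s)
    r1 = likely_region(q, 0.6)
    assert np.array_equal(cumulative_origin_proportion([r1]).values, r1.mask.astype(float))
    assert np.array_equal(
        cumulative_origin_proportion([r1, r1]).values, r1.mask.astype(float)
    )  # idempotent
    r2 = likely_region(quantile_transform(
        make_row_surface([-80.0, -60.0, -40.0, -20.0], y=-20.0, sigma=10.0)), 0.6)
    out = cumulative_origin_proportion([r1, r2])
    assert set(np.unique(out.values)) <= {0.0, 0.5, 1.0}


def test_cumulative_rejects_mismatched_grids(albers):
    from isomove.assignment import LikelyRegion

    s = make_row_surface([-20.0, -40.0], y=-20.0, sigma=10.0)
    r1 = likely_region(quantile_transform(s), 1.0)
    vals = np.zeros((1, 2))
    other = RasterGrid(vals, np.zeros_like(vals, bool), (5.0, 10.0, 10.0, -10.0), albers.crs)
    r2 = LikelyRegion(np.array([[True, False]]), 1.0, "o", other)
    with pytest.raises(ValueError):
        cumulative_origin_proportion([r1, r2])


# --------------------------------------------------- calibration by construction
def test_calibration_by_construction(iso_albers, truth, centroids, cfg, known200):
    """Thresholding the calibrating set itself meets the accuracy floor, and
    the next-larger candidate threshold would drop below it."""
    from isomove import run_origin_pipeline

    res = run_origin_pipeline(iso_albers, known200, [], centroids, cfg)
    qs = []
    from isomove.assignment import _quantile_at_origin, quantile_transform, assignment_surface

    for s in known200:
        surf = quantile_transform(
            assignment_surface(s, res.mu, res.sigma, res.mask)
        )
        qs.append(_quantile_at_origin(surf, s.true_origin))
    qs = np.array(qs)
    coverage = np.mean(qs >= res.threshold)
    assert coverage >= cfg.target_accuracy
    larger = np.unique(qs[qs > res.threshold])
    if larger.size:
        assert np.mean(qs >= larger[0]) < cfg.target_accuracy
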