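"""Season windows, dynamic alpha hulls, range algebra, fatality counts."""

import datetime

import numpy as np
import pytest

from isomove import PipelineConfig, aggregate_fatalities, assign_season, seasonal_ranges
from isomove.alphahull import InsufficientPointsError, dynamic_alpha_hull
from isomove.geodesy import GeoPoint
from isomove.projection import AlbersEqualArea
from isomove.ranges import FatalityRecord, OccurrenceRecord
from isomove.synthetic import make_fatality_fixture


# ------------------------------------------------------------------ seasons
@pytest.mark.parametrize(
    "month,day,season",
    [
        (8, 6, "autumn"),
        (11, 15, "autumn"),
        (3, 15, "winter"),
        (11, 16, "winter"),
        (3, 16, "spring_summer"),
        (8, 5, "spring_summer"),
        (1, 1, "winter"),
        (2, 29, "winter"),
    ],
)
def test_season_window_boundaries(month, day, season):
    year = 2020 if (month, day) != (2, 29) else 2020  # leap year holds Feb 29
    assert assign_season(datetime.date(year, month, day)) == season


@pytest.mark.parametrize("year", [2020, 2021])  # leap and non-leap
def test_season_windows_tile_the_year(year):
    d = datetime.date(year, 1, 1)
    while d.year == year:
        matches = [
            s for s in ("spring_summer", "autumn", "winter") if assign_season(d) == s
        ]
        assert len(matches) == 1
        d += datetime.timedelta(days=1)


# ------------------------------------------------------------------ hulls
def test_triangle_hull_buffers_and_includes_all():
    xy = np.array([[0.0, 0.0], [300.0, 0.0], [150.0, 250.0]])
    res = dynamic_alpha_hull(xy, inclusion=0.95, buffer_km=50.0)
    assert res.inclusion == 1.0
    import shapely

    assert shapely.covers(res.polygon, shapely.points(xy)).all()
    # buffered outward: area strictly exceeds the triangle's
    assert res.polygon.area > 0.5 * 300 * 250


def test_distant_outlier_can_be_excluded():
    rng = np.random.default_rng(1)
    cluster = rng.uniform(0, 100, (19, 2))
    xy = np.vstack([cluster, [2000.0, 2000.0]])
    res = dynamic_alpha_hull(xy, inclusion=0.95, buffer_km=0.0)
    assert res.inclusion >= 0.95
    import shapely

    if not res.used_fallback:
        assert not res.polygon.covers(shapely.Point(2000.0, 2000.0))


def test_tight_cluster_area_dominated_by_buffer():
    rng = np.random.default_rng(2)
    xy = rng.uniform(0, 10, (30, 2))
    res = dynamic_alpha_hull(xy, inclusion=0.95, buffer_km=50.0)
    assert res.polygon.area >= np.pi * 50.0**2


def test_buffer_monotonicity():
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 500, (40, 2))
    areas = [
        dynamic_alpha_hull(xy, inclusion=0.95, buffer_km=b).polygon.area
        for b in (0.0, 25.0, 50.0, 100.0)
    ]
    assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


def test_hull_needs_three_noncollinear_points():
    with pytest.raises(InsufficientPointsError):
        dynamic_alpha_hull(np.array([[0.0, 0.0], [1.0, 1.0]]))
    with pytest.raises(InsufficientPointsError):
        dynamic_alpha_hull(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))


def test_land_constraint_clips_hull():
    from shapely.geometry import box

    xy = np.array([[0.0, 0.0], [300.0, 0.0], [150.0, 250.0]])
    land = box(0.0, 0.0, 150.0, 300.0)
    res = dynamic_alpha_hull(xy, buffer_km=10.0, land=land)
    assert res.polygon.within(land.buffer(1e-6))


# ------------------------------------------------------------ seasonal algebra
def _records(season_dates, pts):
    out = []
    for i, (x, y) in enumerate(pts):
        out.append(OccurrenceRecord(f"c{i}", GeoPoint(x, y), season_dates, None, "t"))
    return out


def _grid_points(w, s, e, n, step):
    xs = np.arange(w, e + 1e-9, step)
    ys = np.arange(s, n + 1e-9, step)
    X, Y = np.meshgrid(xs, ys)
    return list(zip(X.ravel(), Y.ravel()))


SUMMER_DAY = datetime.date(2020, 7, 1)
WINTER_DAY = datetime.date(2020, 1, 15)
AUTUMN_DAY = datetime.date(2020, 9, 20)


def test_identical_summer_winter_sets_make_year_round():
    pts = _grid_points(-90, 30, -85, 34, 1.0)
    records = _records(SUMMER_DAY, pts) + _records(WINTER_DAY, pts) + _records(AUTUMN_DAY, pts)
    cfg = PipelineConfig()
    rs = seasonal_ranges(records, cfg)
    assert rs.areas_km2["year_round"] == pytest.approx(
        rs.areas_km2["spring_summer_hull"], rel=1e-6
    )
    assert rs.areas_km2["spring_summer_only"] == pytest.approx(0.0, abs=1e-6)
    assert rs.areas_km2["winter_only"] == pytest.approx(0.0, abs=1e-6)


def test_disjoint_summer_winter_have_no_year_round():
    summer = _grid_points(-90, 40, -86, 43, 1.0)
    winter = _grid_points(-90, 25, -86, 28, 1.0)
    records = _records(SUMMER_DAY, summer) + _records(WINTER_DAY, winter)
    with pytest.warns(UserWarning):  # autumn has no records
        rs = seasonal_ranges(records, PipelineConfig())
    assert rs.year_round.is_empty
    assert rs.areas_km2["year_round"] == 0.0


def test_nested_squares_difference_area():
    """Autumn strictly containing summer=winter: autumn-only = outer - inner."""
    outer = _grid_points(-92, 30, -84, 38, 0.5)
    inner = _grid_points(-90, 33, -87, 36, 0.5)
    records = (
        _records(AUTUMN_DAY, outer) + _records(SUMMER_DAY, inner) + _records(WINTER_DAY, inner)
    )
    rs = seasonal_ranges(records, PipelineConfig())
    expected = rs.areas_km2["autumn_hull"] - rs.areas_km2["spring_summer_hull"]
    assert rs.areas_km2["autumn_only"] == pytest.approx(expected, rel=1e-6)


def test_range_algebra_conserves_area():
    rng = np.random.default_rng(9)
    records = []
    for day in (SUMMER_DAY, WINTER_DAY, AUTUMN_DAY):
        pts = zip(rng.uniform(-95, -80, 60), rng.uniform(26, 42, 60))
        records += _records(day, list(pts))
    rs = seasonal_ranges(records, PipelineConfig())
    for season in ("spring_summer", "autumn", "winter"):
        others = [s for s in ("spring_summer", "autumn", "winter") if s != season]
        overlap = rs.hulls[season].polygon.intersection(
            rs.hulls[others[0]].polygon.union(rs.hulls[others[1]].polygon)
        )
        total = rs.areas_km2[f"{season}_only"] + overlap.area
        assert total == pytest.approx(rs.areas_km2[f"{season}_hull"], rel=1e-3)


def test_hull_inclusion_asserted_on_every_seasonal_run():
    rng = np.random.default_rng(11)
    records = []
    for day in (SUMMER_DAY, WINTER_DAY, AUTUMN_DAY):
        pts = zip(rng.uniform(-95, -80, 80), rng.uniform(26, 42, 80))
        records += _records(day, list(pts))
    cfg = PipelineConfig()
    rs = seasonal_ranges(records, cfg)
    for season, hull in rs.hulls.items():
        assert hull.used_fallback or hull.inclusion >= cfg.hull_inclusion


def test_season_labelled_records_bypass_dates():
    rec = OccurrenceRecord("c0", GeoPoint(-90, 33), None, "winter", "legacy")
    assert rec.season == "winter"
    with pytest.raises(ValueError):
        OccurrenceRecord("c1", GeoPoint(-90, 33), None, None, "no date or season")
    with pytest.raises(ValueError):
        OccurrenceRecord("c2", GeoPoint(-90, 33), None, "monsoon", "bad label")


# ------------------------------------------------------------------ fatalities
def test_fatality_table_reproduces_published_margins():
    table, by_month = aggregate_fatalities(make_fatality_fixture())
    assert table.loc["Total", "Total"] == 49
    assert table.loc["Total", "Indiana"] == 19
    assert table.loc[2021, "Total"] == 18
    assert table.loc[2020, "Total"] == 19
    assert by_month.to_dict() == {8: 12, 9: 29, 10: 8}


def test_empty_fatality_list_gives_zero_table():
    table, by_month = aggregate_fatalities([])
    assert table.loc["Total", "Total"] == 0
    assert by_month.empty


def test_fatality_record_validation():
    with pytest.raises(ValueError):
        FatalityRecord("Ohio", 2020, "oh_c1", datetime.date(2021, 9, 1))
    with pytest.raises(ValueError):
        FatalityRecord("Ohio", 2020, "oh_c1", datetime.date(2020, 9, 1), "guess")
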