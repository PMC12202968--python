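"""Seasonal range delineation from dated county-centroid occurrence records.

Occurrences are binned into three calendar seasons (spring/summer, autumn,
winter — the windows tile the year exactly), each season's extent of
occurrence is a dynamic alpha hull (single connected polygon covering at
least 95% of the season's points, buffered 50 km, clipped to land), and the
season polygons are combined by overlay algebra: the year-round range is the
summer∩winter overlap, and each season-only range is that season's hull
minus the union of the other seasons' hulls.  Areas are planar km² in the
equal-area frame.  A fatality-count cross-tabulation (state × year, plus
by-month counts) accompanies the ranges.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping
from shapely.geometry.base import BaseGeometry

from .alphahull import HullResult, dynamic_alpha_hull
from .config import SEASON_WINDOWS, PipelineConfig
from .geodesy import GeoPoint
from .projection import AlbersEqualArea, polygon_area_km2

__all__ = [
    "OccurrenceRecord",
    "FatalityRecord",
    "SeasonalRangeSet",
    "SEASONS",
    "assign_season",
    "seasonal_ranges",
    "aggregate_fatalities",
    "read_occurrences_csv",
    "read_fatalities_csv",
    "write_ranges_geojson",
]

SEASONS = ("spring_summer", "autumn", "winter")


@dataclass(frozen=True)
class OccurrenceRecord:
    county_id: str
    centroid: GeoPoint
    date: _dt.date | None = None
    season: str | None = None  # legacy records known only to a season
    source: str = ""

    def __post_init__(self) -> None:
        if self.date is None and self.season is None:
            raise ValueError(f"{self.county_id}: record needs a date or a season label")
        if self.season is not None and self.season not in SEASONS:
            raise ValueError(f"unknown season label {self.season!r}")


@dataclass(frozen=True)
class FatalityRecord:
    state: str
    year: int
    county_id: str
    date: _dt.date
    species_id_method: str = "field"  # field | genetic
    sex: str = "unknown"  # F | M | unknown

    def __post_init__(self) -> None:
        if self.date.year != self.year:
            raise ValueError(f"{self.county_id}: date {self.date} outside year {self.year}")
        if self.species_id_method not in ("field", "genetic"):
            raise ValueError("species_id_method must be 'field' or 'genetic'")
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError("sex must be 'F', 'M' or 'unknown'")


def assign_season(date: _dt.date, windows=None) -> str:
    """Season of a calendar date; window endpoints are inclusive.

    Defaults: spring/summer Mar 16–Aug 5, autumn Aug 6–Nov 15, winter
    Nov 16–Mar 15 (wrapping the new year).
    """
    windows = windows or SEASON_WINDOWS
    md = (date.month, date.day)
    for season, (start, end) in windows.items():
        if start <= end:
            if start <= md <= end:
                return season
        elif md >= start or md <= end:  # year-wrapping window
            return season
    raise ValueError(f"no season window covers {date}")  # unreachable for tiling windows


@dataclass
class SeasonalRangeSet:
    """Per-season hulls, the year-round overlap and season-only remainders."""

    hulls: dict[str, HullResult]
    year_round: BaseGeometry
    season_only: dict[str, BaseGeometry]
    areas_km2: dict[str, float]
    crs: str
    notes: dict[str, str] = field(default_factory=dict)


def _season_of(rec: OccurrenceRecord, windows) -> str:
    return rec.season if rec.season is not None else assign_season(rec.date, windows)


def seasonal_ranges(
    records: list[OccurrenceRecord],
    cfg: PipelineConfig,
    land: BaseGeometry | None = None,
    albers: AlbersEqualArea | None = None,
) -> SeasonalRangeSet:
    """Dynamic alpha hull per season plus the year-round / season-only algebra.

    ``land`` is a planar polygon in the same Albers frame; seasons with fewer
    than 3 records are reported empty with a warning.  The winter-only
    remainder is computed like the others but flagged in ``notes`` (it is
    vanishingly small for this species and excluded from downstream use).
    """
    albers = albers or AlbersEqualArea(
        cfg.albers_lat1, cfg.albers_lat2, cfg.albers_lat0, cfg.albers_lon0
    )
    by_season: dict[str, list[GeoPoint]] = {s: [] for s in SEASONS}
    for rec in records:
        by_season[_season_of(rec, cfg.season_windows)].append(rec.centroid)

    hulls: dict[str, HullResult] = {}
    for season, pts in by_season.items():
        if len(pts) < 3:
            warnings.warn(f"{season}: fewer than 3 records; season reported empty", stacklevel=2)
            hulls[season] = HullResult(Polygon(), np.nan, 0.0, False, len(pts))
            continue
        xy = np.array([albers.forward(p.lon, p.lat) for p in pts])
        hulls[season] = dynamic_alpha_hull(
            xy, inclusion=cfg.hull_inclusion, buffer_km=cfg.hull_buffer_km, land=land
        )

    summer = hulls["spring_summer"].polygon
    winter = hulls["winter"].polygon
    year_round = summer.intersection(winter)
    season_only = {}
    for season in SEASONS:
        others = [hulls[s].polygon for s in SEASONS if s != season]
        season_only[season] = hulls[season].polygon.difference(others[0].union(others[1]))

    crs = albers.crs
    areas = {f"{s}_hull": polygon_area_km2(hulls[s].polygon, crs) for s in SEASONS}
    areas["year_round"] = polygon_area_km2(year_round, crs)
    for s in SEASONS:
        areas[f"{s}_only"] = polygon_area_km2(season_only[s], crs)
    notes = {
        "winter_only": "computed but reported separately; excluded from downstream analyses"
    }
    return SeasonalRangeSet(hulls, year_round, season_only, areas, crs, notes)


def aggregate_fatalities(records: list[FatalityRecord]):
    """Exact state × year cross-tabulation with totals, plus counts by month.

    Returns ``(table, by_month)``: a DataFrame (years as rows, states as
    columns, 'Total' margins) and a month-indexed Series.
    """
    if not records:
        empty = pd.DataFrame({"Total": [0]}, index=pd.Index(["Total"], name="year"))
        return empty, pd.Series(dtype=int, name="count")
    df = pd.DataFrame(
        {"state": r.state, "year": r.year, "month": r.date.month} for r in records
    )
    table = pd.crosstab(df["year"], df["state"], margins=True, margins_name="Total")
    by_month = df["month"].value_counts().sort_index().rename("count")
    return table, by_month


# ------------------------------------------------------------------- I/O
def read_occurrences_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Columns: county_id, lon, lat, date (ISO) or season, source."""
    df = pd.read_csv(path)
    out = []
    for rec in df.itertuples(index=False):
        date = None
        season = None
        raw_date = getattr(rec, "date", None)
        if isinstance(raw_date, str) and raw_date:
            date = _dt.date.fromisoformat(raw_date)
        raw_season = getattr(rec, "season", None)
        if isinstance(raw_season, str) and raw_season:
            season = raw_season
        out.append(
            OccurrenceRecord(
                str(rec.county_id),
                GeoPoint(float(rec.lon), float(rec.lat)),
                date,
                season,
                str(getattr(rec, "source", "")),
            )
        )
    return out


def read_fatalities_csv(path: str | Path) -> list[FatalityRecord]:
    """Columns: state, year, county_id, date, species_id_method, sex."""
    df = pd.read_csv(path)
    return [
        FatalityRecord(
            str(r.state),
            int(r.year),
            str(r.county_id),
            _dt.date.fromisoformat(str(r.date)),
            str(r.species_id_method),
            str(r.sex),
        )
        for r in df.itertuples(index=False)
    ]


def _to_lonlat(geom: BaseGeometry, albers: AlbersEqualArea) -> dict:
    """GeoJSON-style mapping with planar km coordinates unprojected to degrees."""
    import shapely

    def _tx(coords):
        arr = np.asarray(coords)
        lon, lat = albers.inverse(arr[:, 0], arr[:, 1])
        return np.column_stack([lon, lat])

    return mapping(shapely.transform(geom, _tx))


def write_ranges_geojson(ranges: SeasonalRangeSet, path: str | Path) -> None:
    """One feature per season hull / season-only remainder / year-round overlap.

    Coordinates are written in geographic degrees (GeoJSON convention); each
    feature carries its planar area_km2 property.
    """
    albers = AlbersEqualArea.from_crs(ranges.crs)
    features = []
    for season in SEASONS:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "name": f"{season}_hull",
                    "area_km2": ranges.areas_km2[f"{season}_hull"],
                    "alpha_km": None
                    if not np.isfinite(ranges.hulls[season].alpha_km)
                    else ranges.hulls[season].alpha_km,
                    "inclusion": ranges.hulls[season].inclusion,
                },
                "geometry": _to_lonlat(ranges.hulls[season].polygon, albers),
            }
        )
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "name": f"{season}_only",
                    "area_km2": ranges.areas_km2[f"{season}_only"],
                    "note": ranges.notes.get(f"{season}_only", ""),
                },
                "geometry": _to_lonlat(ranges.season_only[season], albers),
            }
        )
    features.append(
        {
            "type": "Feature",
            "properties": {"name": "year_round", "area_km2": ranges.areas_km2["year_round"]},
            "geometry": _to_lonlat(ranges.year_round, albers),
        }
    )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
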