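"""Synthetic inputs with the statistical structure the pipeline assumes.

Real inputs — the continental precipitation isoscape, molt-window
known-origin fur samples, carcass fur samples, and the occurrence-record
compilation — are emulated so every stage is testable offline:

* an isoscape whose δ²H_precip decreases linearly with latitude plus
  Gaussian spatial noise (the dominant continental pattern);
* known-origin samples whose fur values follow the linear rescaling of the
  origin cell's precipitation value plus noise combining the calibration
  residual and the 2.3‰ analytical precision in quadrature, with collection
  dates inside the molt window (June 14 – August 7);
* migrant samples whose fur reflects an origin displaced along the
  ellipsoid (default: carcass site due north of the origin), so that the
  true direction and displacement are known;
* occurrence records drawn uniformly from known seasonal truth polygons
  with dates uniform in the season windows; and
* the deterministic fatality-count fixture reproducing the published
  state × year monitoring table.

Identical truth + seed always yields identical datasets.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, box

from .calibration import FurSample, Isoscape, RescalingFunction, write_samples_csv
from .config import SEASON_WINDOWS, PipelineConfig
from .geodesy import GeoPoint, destination
from .projection import GEOGRAPHIC_CRS
from .raster import RasterGrid
from .ranges import FatalityRecord, OccurrenceRecord

__all__ = [
    "SyntheticTruth",
    "make_isoscape",
    "make_known_origin_samples",
    "make_migrant_samples",
    "make_occurrences",
    "make_fatality_fixture",
    "make_county_centroids",
    "write_input_bundle",
    "MOLT_WINDOW",
]

MOLT_WINDOW = (_dt.date(2020, 6, 14), _dt.date(2020, 8, 7))


def _default_season_polys() -> dict[str, Polygon]:
    # lon/lat boxes nested like the real seasonal ranges: a small southern
    # winter core, a summer range reaching further north, and a much larger
    # autumn range extending north and west.  winter ⊂ summer, so the
    # winter-only remainder is empty (mirroring the < 1 km² finding).
    return {
        "winter": box(-95.0, 26.0, -78.0, 33.0),
        "spring_summer": box(-97.0, 25.0, -77.0, 38.0),
        "autumn": box(-100.0, 25.0, -75.0, 45.0),
    }


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind every synthetic dataset."""

    # isoscape: value = base + gradient * lat + N(0, noise_sd)
    iso_base_permil: float = -10.0
    iso_gradient_permil_per_deg: float = -1.5
    iso_noise_sd_permil: float = 3.0
    # fur ~ precip rescaling truth
    beta0: float = -40.0
    beta1: float = 0.6
    residual_sd: float = 10.0
    analytical_precision: float = 2.3
    # migrant displacement: site = destination(origin, azimuth, distance)
    migrant_distance_km: float = 500.0
    migrant_azimuth_deg: float = 0.0  # due north: origins lie south of sites
    season_polygons: dict[str, Polygon] = field(default_factory=_default_season_polys)
    extent: tuple[float, float, float, float] = (-100.0, 24.0, -70.0, 48.0)  # W, S, E, N
    seed: int = 0

    def rescaling(self) -> RescalingFunction:
        return RescalingFunction(self.beta0, self.beta1, self.residual_sd, 3)

    def sample_noise_sd(self) -> float:
        return float(np.hypot(self.residual_sd, self.analytical_precision))


def make_isoscape(
    extent: tuple[float, float, float, float],
    resolution_deg: float,
    truth: SyntheticTruth,
) -> Isoscape:
    """Latitude-gradient isoscape on a geographic grid.

    With zero noise the surface is strictly monotone in latitude (perfectly
    rank-correlated), which makes assignment geometry easy to reason about
    in tests.
    """
    w, s, e, n = extent
    if not (e > w and n > s):
        raise ValueError("degenerate extent")
    if resolution_deg <= 0:
        raise ValueError("resolution must be positive")
    nc = int(round((e - w) / resolution_deg))
    nr = int(round((n - s) / resolution_deg))
    transform = (w, n, resolution_deg, -resolution_deg)
    grid = RasterGrid(np.zeros((nr, nc)), np.zeros((nr, nc), dtype=bool), transform, GEOGRAPHIC_CRS)
    _, LAT = grid.cell_centers()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x150]))
    vals = (
        truth.iso_base_permil
        + truth.iso_gradient_permil_per_deg * LAT
        + rng.normal(0.0, truth.iso_noise_sd_permil, size=LAT.shape)
    )
    grid.values = vals
    return Isoscape(grid)


def _uniform_cells(iso: Isoscape, n: int, rng, within: Polygon | None = None):
    """Uniform draws of unmasked cell centers (optionally inside a polygon)."""
    import shapely

    LON, LAT = iso.grid.centers_lonlat()
    ok = ~iso.grid.nodata_mask
    if within is not None:
        ok &= shapely.contains_xy(within, LON, LAT)
    lon, lat = LON[ok], LAT[ok]
    if lon.size == 0:
        raise ValueError("no candidate origin cells")
    idx = rng.integers(0, lon.size, size=n)
    return lon[idx], lat[idx]


def _molt_dates(n: int, rng) -> list[_dt.date]:
    span = (MOLT_WINDOW[1] - MOLT_WINDOW[0]).days
    return [MOLT_WINDOW[0] + _dt.timedelta(days=int(d)) for d in rng.integers(0, span + 1, n)]


def make_known_origin_samples(
    iso: Isoscape,
    truth: SyntheticTruth,
    n: int,
    seed: int,
    within: Polygon | None = None,
) -> list[FurSample]:
    """Known-origin calibration/test samples: site == origin, molt-window dates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    lon, lat = _uniform_cells(iso, n, rng, within)
    precip = np.array([iso.value_at_point(GeoPoint(x, y)) for x, y in zip(lon, lat)])
    fur = truth.beta0 + truth.beta1 * precip + rng.normal(0.0, truth.sample_noise_sd(), n)
    fur = np.clip(fur, -299.9, 49.9)
    dates = _molt_dates(n, rng)
    return [
        FurSample(f"ko{i:04d}", float(fur[i]), GeoPoint(float(lon[i]), float(lat[i])), dates[i],
                  GeoPoint(float(lon[i]), float(lat[i])))
        for i in range(n)
    ]


def make_migrant_samples(
    iso: Isoscape,
    truth: SyntheticTruth,
    n: int,
    seed: int,
    within: Polygon | None = None,
) -> list[FurSample]:
    """Migrant carcass samples: fur from the origin, carcass displaced away.

    The origin is drawn on-grid (optionally inside ``within``, e.g. the known
    range); the carcass site is the ellipsoid destination at the truth's
    displacement.  Sites may leave the grid or the range mask — carcasses in
    autumn are found outside the known range — but samples whose *origin*
    would leave the grid are skipped with a warning.
    """
    import warnings

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x316]))
    lon, lat = _uniform_cells(iso, n, rng, within)
    site_lon, site_lat = destination(
        lon, lat, truth.migrant_azimuth_deg, truth.migrant_distance_km * 1000.0
    )
    precip = np.array([iso.value_at_point(GeoPoint(x, y)) for x, y in zip(lon, lat)])
    bad = ~np.isfinite(precip)
    if bad.any():
        warnings.warn(f"skipped {int(bad.sum())} migrant(s) with off-grid origins", stacklevel=2)
    fur = truth.beta0 + truth.beta1 * precip + rng.normal(0.0, truth.sample_noise_sd(), n)
    out = []
    autumn0 = _dt.date(2020, 8, 6)
    for i in range(n):
        if bad[i]:
            continue
        date = autumn0 + _dt.timedelta(days=int(rng.integers(0, 70)))
        out.append(
            FurSample(
                f"mig{i:04d}",
                float(np.clip(fur[i], -299.9, 49.9)),
                GeoPoint(float(site_lon[i]), float(site_lat[i])),
                date,
                GeoPoint(float(lon[i]), float(lat[i])),
            )
        )
    return out


def make_occurrences(
    truth: SyntheticTruth, n_per_season: int, seed: int
) -> list[OccurrenceRecord]:
    """Occurrence records uniform in each season's truth polygon and window."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0CC]))
    out = []
    for season, poly in truth.season_polygons.items():
        w, s, e, n = poly.bounds
        pts: list[tuple[float, float]] = []
        import shapely

        while len(pts) < n_per_season:
            m = 4 * (n_per_season - len(pts))
            xs = rng.uniform(w, e, m)
            ys = rng.uniform(s, n, m)
            inside = shapely.contains_xy(poly, xs, ys)
            pts.extend(zip(xs[inside], ys[inside]))
        pts = pts[:n_per_season]
        dates = _season_dates(season, n_per_season, rng)
        for i, ((x, y), d) in enumerate(zip(pts, dates)):
            out.append(
                OccurrenceRecord(f"{season[:3]}{i:04d}", GeoPoint(float(x), float(y)), d,
                                 None, "synthetic")
            )
    return out


def _season_dates(season: str, n: int, rng) -> list[_dt.date]:
    (m1, d1), (m2, d2) = SEASON_WINDOWS[season]
    start = _dt.date(2020, m1, d1)
    end = _dt.date(2020 if (m2, d2) >= (m1, d1) else 2021, m2, d2)
    span = (end - start).days
    return [start + _dt.timedelta(days=int(k)) for k in rng.integers(0, span + 1, n)]


# ---------------------------------------------------------------- fatalities
_TABLE_COUNTS = {  # published state × year monitoring counts
    2019: {"Indiana": 7},
    2020: {"Illinois": 3, "Indiana": 9, "Ohio": 7},
    2021: {"Illinois": 2, "Indiana": 2, "Michigan": 4, "Ohio": 10},
    2022: {"Iowa": 2, "Illinois": 1, "Indiana": 1, "Maryland": 1},
}


def make_fatality_fixture() -> list[FatalityRecord]:
    """Deterministic 49-record fixture matching the published count table.

    State × year counts reproduce the monitoring table exactly (grand total
    49); discovery months are assigned so the by-month totals are 12 in
    August, 29 in September and 8 in October, with the first and last
    discovery dates August 2 and October 13.
    """
    records = []
    k = 0
    months = ["Aug"] * 12 + ["Sep"] * 29 + ["Oct"] * 8
    month_num = {"Aug": 8, "Sep": 9, "Oct": 10}
    genetic_quota = 10  # molecular confirmations, all from the fur-sample cohort
    sexes = ["F", "F", "F", "F", "F", "M", "M", "M", "M", "unknown"]
    g = 0
    for year in sorted(_TABLE_COUNTS):
        for state in sorted(_TABLE_COUNTS[year]):
            for i in range(_TABLE_COUNTS[year][state]):
                mon = month_num[months[k]]
                day = 2 + (k * 7) % 26 if mon == 8 else (1 + (k * 5) % 28 if mon == 9 else 1 + k % 13)
                if k == 0:
                    mon, day = 8, 2
                if k == 48:
                    mon, day = 10, 13
                method = "field"
                sex = "unknown"
                if year == 2020 and g < genetic_quota:
                    method = "genetic"
                    sex = sexes[g]
                    g += 1
                records.append(
                    FatalityRecord(state, year, f"{state[:2].lower()}_c{i}",
                                   _dt.date(year, mon, day), method, sex)
                )
                k += 1
    return records


def make_county_centroids(truth: SyntheticTruth, spacing_deg: float = 1.0) -> list[GeoPoint]:
    """Regular lattice of 'county centroids' across the known (summer) range."""
    poly = truth.season_polygons["spring_summer"]
    import shapely

    w, s, e, n = poly.bounds
    xs = np.arange(w + spacing_deg / 2, e, spacing_deg)
    ys = np.arange(s + spacing_deg / 2, n, spacing_deg)
    X, Y = np.meshgrid(xs, ys)
    ok = shapely.contains_xy(poly, X.ravel(), Y.ravel())
    return [GeoPoint(float(x), float(y)) for x, y in zip(X.ravel()[ok], Y.ravel()[ok])]


def write_input_bundle(
    truth: SyntheticTruth,
    outdir: str | Path,
    resolution_deg: float = 0.5,
    n_known: int = 200,
    n_migrant: int = 17,
    n_occ_per_season: int = 200,
    cfg: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Write every pipeline input to a directory; returns the path map."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or PipelineConfig(random_seed=truth.seed)
    iso = make_isoscape(truth.extent, resolution_deg, truth)
    summer = truth.season_polygons["spring_summer"]
    known = make_known_origin_samples(iso, truth, n_known, truth.seed, within=summer)
    migrants = make_migrant_samples(iso, truth, n_migrant, truth.seed + 1, within=summer)
    occ = make_occurrences(truth, n_occ_per_season, truth.seed)
    fat = make_fatality_fixture()
    centroids = make_county_centroids(truth)

    paths = {k: outdir / v for k, v in {
        "isoscape": "isoscape.asc",
        "known": "known_origin_samples.csv",
        "migrants": "carcass_samples.csv",
        "occurrences": "occurrences.csv",
        "fatalities": "fatalities.csv",
        "centroids": "county_centroids.csv",
        "land": "land.geojson",
        "truth_ranges": "truth_ranges.geojson",
        "config": "config.yaml",
    }.items()}
    iso.grid.write_ascii(paths["isoscape"])
    write_samples_csv(known, paths["known"])
    write_samples_csv(migrants, paths["migrants"])
    pd.DataFrame(
        {
            "county_id": r.county_id,
            "lon": r.centroid.lon,
            "lat": r.centroid.lat,
            "date": r.date.isoformat() if r.date else "",
            "season": r.season or "",
            "source": r.source,
        }
        for r in occ
    ).to_csv(paths["occurrences"], index=False)
    pd.DataFrame(
        {
            "state": r.state,
            "year": r.year,
            "county_id": r.county_id,
            "date": r.date.isoformat(),
            "species_id_method": r.species_id_method,
            "sex": r.sex,
        }
        for r in fat
    ).to_csv(paths["fatalities"], index=False)
    pd.DataFrame({"lon": [c.lon for c in centroids], "lat": [c.lat for c in centroids]}).to_csv(
        paths["centroids"], index=False
    )
    import json

    from shapely.geometry import mapping

    w, s, e, n = truth.extent
    land = box(w, s, e, n)
    paths["land"].write_text(
        json.dumps({"type": "Feature", "properties": {"name": "land"}, "geometry": mapping(land)})
    )
    paths["truth_ranges"].write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "properties": {"season": sname},
                        "geometry": mapping(poly),
                    }
                    for sname, poly in truth.season_polygons.items()
                ],
            }
        )
    )
    cfg.to_yaml(paths["config"])
    return paths
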