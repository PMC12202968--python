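"""Per-sample migration statistics: direction of origin and minimum travel.

Direction is classified by a probability-weighted bootstrap: candidate
origins are drawn from the probability-of-origin surface, the travel azimuth
(shortest ellipsoid path from the drawn origin toward the carcass site) is
computed for each draw, and a replication indicates a *southerly origin*
when that azimuth points north (|azimuth| < 90°).  A sample is called south
(or north) when more than the configured majority — 75% by default — of
replications agree; otherwise it stays unclassified.  Minimum travel is the
shortest ellipsoid distance from the carcass site to any cell center of the
sample's likely region, a deliberately conservative lower bound on the
distance actually flown.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .assignment import LikelyRegion, ProbabilitySurface, NoDomainError
from .config import PipelineConfig
from .geodesy import GeoPoint, inverse
from .projection import GEOGRAPHIC_CRS, AlbersEqualArea

__all__ = [
    "DirectionSummary",
    "TravelEstimate",
    "sample_origin_cells",
    "classify_direction",
    "min_travel_distance",
    "sample_rng",
]


@dataclass(frozen=True)
class DirectionSummary:
    sample_id: str
    n_reps: int
    frac_south: float
    category: str  # south | north | unclassified
    seed: int
    n_excluded: int = 0


@dataclass(frozen=True)
class TravelEstimate:
    sample_id: str
    min_distance_km: float
    nearest_cell: GeoPoint


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample RNG stream derived from the run seed and the sample id.

    Streams are keyed by a CRC32 of the id, so reordering samples cannot
    change any sample's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode("utf8"))])
    )


def _centers_lonlat(surface: ProbabilitySurface) -> tuple[np.ndarray, np.ndarray]:
    grid = surface.grid
    X, Y = grid.cell_centers()
    if grid.crs == GEOGRAPHIC_CRS:
        return X, Y
    return AlbersEqualArea.from_crs(grid.crs).inverse(X, Y)


def _draw_cells(surface: ProbabilitySurface, n_reps: int, rng: np.random.Generator):
    """Weighted draws of flat cell indices plus the domain's lon/lat centers."""
    domain = ~surface.grid.nodata_mask
    p = surface.grid.values[domain]
    if p.sum() <= 0:
        raise NoDomainError(f"{surface.sample_id}: surface carries no mass")
    lon, lat = _centers_lonlat(surface)
    idx = rng.choice(p.size, size=n_reps, replace=True, p=p / p.sum())
    return idx, lon[domain], lat[domain]


def sample_origin_cells(
    surface: ProbabilitySurface, n_reps: int, seed: int
) -> list[GeoPoint]:
    """IID draws of cell centers, probability proportional to cell mass."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    idx, lon, lat = _draw_cells(surface, n_reps, sample_rng(seed, surface.sample_id))
    return [GeoPoint(float(lon[i]), float(lat[i])) for i in idx]


def classify_direction(
    surface: ProbabilitySurface,
    site: GeoPoint,
    cfg: PipelineConfig,
    n_reps: int | None = None,
) -> DirectionSummary:
    """Bootstrap direction-of-origin call for one sample.

    Draws n_reps origins weighted by the surface; bearings are computed once
    per distinct drawn cell.  Replications whose drawn origin coincides with
    the site are excluded; bearings exactly at the cutoff count to neither
    side.
    """
    n = cfg.n_bootstrap if n_reps is None else n_reps
    if n < 1:
        raise ValueError("n_reps must be >= 1")
    rng = sample_rng(cfg.random_seed, surface.sample_id)
    idx, lon, lat = _draw_cells(surface, n, rng)
    uniq, counts = np.unique(idx, return_counts=True)
    ulon, ulat = lon[uniq], lat[uniq]
    if cfg.bearing_convention == "travel":
        _, az = inverse(ulon, ulat, site.lon, site.lat)  # origin -> site
        south = np.abs(az) < cfg.bearing_cutoff_deg
        north = np.abs(az) > cfg.bearing_cutoff_deg
    else:  # azimuth site -> origin: southerly origin points south
        _, az = inverse(site.lon, site.lat, ulon, ulat)
        south = np.abs(az) > cfg.bearing_cutoff_deg
        north = np.abs(az) < cfg.bearing_cutoff_deg
    coincident = (ulon == site.lon) & (ulat == site.lat)
    n_excl = int(counts[coincident].sum())
    use = ~coincident
    n_used = int(counts[use].sum())
    if n_used == 0:
        raise NoDomainError(f"{surface.sample_id}: every replication coincided with the site")
    frac_south = float(counts[use & south].sum() / n_used)
    frac_north = float(counts[use & north].sum() / n_used)
    if frac_south > cfg.direction_fraction:
        category = "south"
    elif frac_north > cfg.direction_fraction:
        category = "north"
    else:
        category = "unclassified"
    return DirectionSummary(surface.sample_id, n, frac_south, category, cfg.random_seed, n_excl)


def exact_direction_fraction(surface: ProbabilitySurface, site: GeoPoint, cfg: PipelineConfig) -> float:
    """Mass-weighted southerly fraction by direct summation over cells.

    The n→∞ limit of :func:`classify_direction`; used as its own cross-check.
    """
    domain = ~surface.grid.nodata_mask
    p = surface.grid.values[domain]
    lon, lat = _centers_lonlat(surface)
    lon, lat = lon[domain], lat[domain]
    keep = ~((lon == site.lon) & (lat == site.lat))
    if cfg.bearing_convention == "travel":
        _, az = inverse(lon[keep], lat[keep], site.lon, site.lat)
        south = np.abs(az) < cfg.bearing_cutoff_deg
    else:
        _, az = inverse(site.lon, site.lat, lon[keep], lat[keep])
        south = np.abs(az) > cfg.bearing_cutoff_deg
    w = p[keep]
    return float(w[south].sum() / w.sum())


def min_travel_distance(site: GeoPoint, region: LikelyRegion) -> TravelEstimate:
    """Shortest ellipsoid distance from the site to a likely cell center.

    Ties go to the first likely cell in row-major order.
    """
    if not region.mask.any():
        raise ValueError(f"{region.sample_id}: empty likely region")
    grid = region.grid
    X, Y = grid.cell_centers()
    if grid.crs == GEOGRAPHIC_CRS:
        lon, lat = X, Y
    else:
        lon, lat = AlbersEqualArea.from_crs(grid.crs).inverse(X, Y)
    lon, lat = lon[region.mask], lat[region.mask]
    d, _ = inverse(site.lon, site.lat, lon, lat)
    i = int(np.argmin(d))  # argmin returns the first minimum: row-major tie-break
    return TravelEstimate(
        region.sample_id, float(d[i]) / 1000.0, GeoPoint(float(lon[i]), float(lat[i]))
    )
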