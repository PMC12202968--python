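"""Ellipsoidal geodesy on WGS84: distances, azimuths and destination points.

Distance and bearing between carcass sites and candidate origin cells are the
backbone of the movement summaries, and both are defined on the reference
ellipsoid (shortest ellipsoid path), not on a sphere.  The inverse and direct
problems are solved with Vincenty's iterative formulae, which converge to
sub-millimetre accuracy everywhere except nearly antipodal pairs; for the
continental scales this package deals with that regime is never reached, but a
spherical fallback is applied rather than failing if an input pair does not
converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoPoint",
    "WGS84_A",
    "WGS84_F",
    "geodesic_distance",
    "geodesic_bearing",
    "inverse",
    "destination",
]

WGS84_A = 6_378_137.0  # semi-major axis, metres
WGS84_F = 1.0 / 298.257223563  # flattening
_B = WGS84_A * (1.0 - WGS84_F)  # semi-minor axis
_MEAN_R = (2.0 * WGS84_A + _B) / 3.0


class CoordinateError(ValueError):
    """Longitude/latitude outside the valid range."""


class UndefinedBearingError(ValueError):
    """Bearing requested between coincident points."""


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position in decimal degrees (east, north)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise CoordinateError(f"non-finite coordinates ({self.lon}, {self.lat})")
        if not (-180.0 <= self.lon <= 180.0):
            raise CoordinateError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise CoordinateError(f"latitude {self.lat} outside [-90, 90]")


def _normalize_az(az_deg: np.ndarray) -> np.ndarray:
    """Wrap azimuths into (-180, 180], 0 = due north."""
    az = (np.asarray(az_deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(az == -180.0, 180.0, az)


def inverse(
    lon1, lat1, lon2, lat2, *, tol: float = 1e-12, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the geodesic inverse problem (vectorized Vincenty).

    Returns ``(distance_m, azimuth1_deg)`` where the azimuth is the initial
    heading of the shortest ellipsoid path at point 1, in (-180, 180] with
    0 = north.  Coincident pairs return distance 0 and azimuth ``nan``.
    """
    lon1, lat1, lon2, lat2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    )
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1.0 - WGS84_F) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(np.radians(lat2)))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)
    converged = np.zeros(lam.shape, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        ss = np.hypot(t1, t2)
        cs = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sg = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss != 0.0, cosU1 * cosU2 * sin_lam / ss, 0.0)
        csa = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2 = np.where(csa != 0.0, cs - 2.0 * sinU1 * sinU2 / np.where(csa == 0, 1, csa), 0.0)
        C = WGS84_F / 16.0 * csa * (4.0 + WGS84_F * (4.0 - 3.0 * csa))
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sg + C * ss * (c2 + C * cs * (-1.0 + 2.0 * c2**2))
        )
        upd = active
        sin_sigma = np.where(upd, ss, sin_sigma)
        cos_sigma = np.where(upd, cs, cos_sigma)
        sigma = np.where(upd, sg, sigma)
        cos_sq_alpha = np.where(upd, csa, cos_sq_alpha)
        cos2sm = np.where(upd, c2, cos2sm)
        done = np.abs(lam_new - lam) < tol
        converged |= active & done
        lam = np.where(active, lam_new, lam)
        active = active & ~done

    u_sq = cos_sq_alpha * (WGS84_A**2 - _B**2) / _B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    Bc = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        Bc
        * sin_sigma
        * (
            cos2sm
            + Bc
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos2sm**2)
                - Bc
                / 6.0
                * cos2sm
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos2sm**2)
            )
        )
    )
    dist = _B * A * (sigma - delta_sigma)

    az = np.degrees(
        np.arctan2(
            cosU2 * np.sin(lam),
            cosU1 * sinU2 - sinU1 * cosU2 * np.cos(lam),
        )
    )
    az = _normalize_az(az)

    coincident = (lon1 == lon2) & (lat1 == lat2)
    dist = np.where(coincident, 0.0, dist)
    az = np.where(coincident, np.nan, az)

    # Spherical fallback for (near-antipodal) non-convergence.
    bad = ~converged & ~coincident
    if bad.any():
        sph_d, sph_az = _spherical_inverse(lon1, lat1, lon2, lat2)
        dist = np.where(bad, sph_d, dist)
        az = np.where(bad, sph_az, az)
    return dist, az


def _spherical_inverse(lon1, lat1, lon2, lat2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    d = _MEAN_R * np.arccos(
        np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
    )
    az = np.degrees(
        np.arctan2(
            np.sin(dl) * np.cos(p2),
            np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl),
        )
    )
    return d, _normalize_az(az)


def destination(lon, lat, azimuth_deg, distance_m) -> tuple[np.ndarray, np.ndarray]:
    """Solve the geodesic direct problem (vectorized Vincenty).

    Starting at (lon, lat), travel ``distance_m`` along the initial heading
    ``azimuth_deg``; returns the destination ``(lon, lat)`` in degrees.
    """
    lon, lat, az, s = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lon, lat, azimuth_deg, distance_m))
    )
    alpha1 = np.radians(az)
    U1 = np.arctan((1.0 - WGS84_F) * np.tan(np.radians(lat)))
    sigma1 = np.arctan2(np.tan(U1), np.cos(alpha1))
    sin_alpha = np.cos(U1) * np.sin(alpha1)
    cos_sq_alpha = 1.0 - sin_alpha**2
    u_sq = cos_sq_alpha * (WGS84_A**2 - _B**2) / _B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    Bc = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))

    sigma = s / (_B * A)
    for _ in range(200):
        cos2sm = np.cos(2.0 * sigma1 + sigma)
        sin_s, cos_s = np.sin(sigma), np.cos(sigma)
        delta = (
            Bc
            * sin_s
            * (
                cos2sm
                + Bc
                / 4.0
                * (
                    cos_s * (-1.0 + 2.0 * cos2sm**2)
                    - Bc / 6.0 * cos2sm * (-3.0 + 4.0 * sin_s**2) * (-3.0 + 4.0 * cos2sm**2)
                )
            )
        )
        sigma_new = s / (_B * A) + delta
        if np.all(np.abs(sigma_new - sigma) < 1e-12):
            sigma = sigma_new
            break
        sigma = sigma_new

    sin_s, cos_s = np.sin(sigma), np.cos(sigma)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    tmp = sinU1 * sin_s - cosU1 * cos_s * np.cos(alpha1)
    lat2 = np.arctan2(
        sinU1 * cos_s + cosU1 * sin_s * np.cos(alpha1),
        (1.0 - WGS84_F) * np.hypot(sin_alpha, tmp),
    )
    lam = np.arctan2(sin_s * np.sin(alpha1), cosU1 * cos_s - sinU1 * sin_s * np.cos(alpha1))
    C = WGS84_F / 16.0 * cos_sq_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha))
    cos2sm = np.cos(2.0 * sigma1 + sigma)
    L = lam - (1.0 - C) * WGS84_F * sin_alpha * (
        sigma + C * sin_s * (cos2sm + C * cos_s * (-1.0 + 2.0 * cos2sm**2))
    )
    lon2 = (lon + np.degrees(L) + 540.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Shortest-path distance between two points on the WGS84 ellipsoid, km."""
    d, _ = inverse(a.lon, a.lat, b.lon, b.lat)
    return float(d) / 1000.0


def geodesic_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Initial azimuth at ``a`` of the shortest ellipsoid path to ``b``.

    Degrees in (-180, 180], 0 = due north.  Raises for coincident points,
    where the bearing is undefined.
    """
    if a.lon == b.lon and a.lat == b.lat:
        raise UndefinedBearingError("bearing undefined between coincident points")
    _, az = inverse(a.lon, a.lat, b.lon, b.lat)
    return float(az)
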