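"""Albers equal-area conic projection on the WGS84 ellipsoid.

Probability-of-origin surfaces are normalized per cell, which is only
meaningful when every cell covers the same ground area; range areas are
likewise planar areas in an equal-area frame.  Both therefore run in an
Albers equal-area conic projection centered on eastern North America.  The
standard parallels and origin are configurable; the defaults are the common
conterminous-US parameterization (29.5/45.5, origin 23N 96W).

Forward/inverse formulas follow the standard ellipsoidal development
(authalic-latitude series solved iteratively).  Coordinates are in km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodesy import WGS84_A, WGS84_F

__all__ = ["AlbersEqualArea", "GEOGRAPHIC_CRS", "polygon_area_km2", "MustProjectError"]

GEOGRAPHIC_CRS = "EPSG:4326"

_E2 = WGS84_F * (2.0 - WGS84_F)
_E = np.sqrt(_E2)


class MustProjectError(ValueError):
    """Planar operation attempted on geographic (degree) coordinates."""


def _q(sin_phi: np.ndarray) -> np.ndarray:
    """Authalic function q(phi) (Snyder 3-12)."""
    es = _E * sin_phi
    return (1.0 - _E2) * (
        sin_phi / (1.0 - _E2 * sin_phi**2) - (1.0 / (2.0 * _E)) * np.log((1.0 - es) / (1.0 + es))
    )


def _m(phi: np.ndarray) -> np.ndarray:
    return np.cos(phi) / np.sqrt(1.0 - _E2 * np.sin(phi) ** 2)


@dataclass(frozen=True)
class AlbersEqualArea:
    """Equal-area conic with two standard parallels; units are km."""

    lat1: float = 29.5
    lat2: float = 45.5
    lat0: float = 23.0
    lon0: float = -96.0

    def __post_init__(self) -> None:
        p1, p2 = np.radians(self.lat1), np.radians(self.lat2)
        n = (_m(p1) ** 2 - _m(p2) ** 2) / (_q(np.sin(p2)) - _q(np.sin(p1)))
        object.__setattr__(self, "_n", float(n))
        object.__setattr__(self, "_C", float(_m(p1) ** 2 + n * _q(np.sin(p1))))
        object.__setattr__(self, "_rho0", float(self._rho(np.radians(self.lat0))))

    def _rho(self, phi):
        return WGS84_A * np.sqrt(self._C - self._n * _q(np.sin(phi))) / self._n

    @property
    def crs(self) -> str:
        return f"albers:{self.lat1}:{self.lat2}:{self.lat0}:{self.lon0}:km"

    @classmethod
    def from_crs(cls, crs: str) -> "AlbersEqualArea":
        parts = crs.split(":")
        if parts[0] != "albers" or len(parts) != 6 or parts[5] != "km":
            raise ValueError(f"not an Albers crs string: {crs!r}")
        return cls(*(float(p) for p in parts[1:5]))

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Degrees -> (x, y) km."""
        lon = np.asarray(lon, dtype=float)
        phi = np.radians(np.asarray(lat, dtype=float))
        rho = self._rho(phi)
        theta = self._n * np.radians(lon - self.lon0)
        x = rho * np.sin(theta)
        y = self._rho0 - rho * np.cos(theta)
        return x / 1000.0, y / 1000.0

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) km -> degrees, inverting the authalic latitude iteratively."""
        x = np.asarray(x, dtype=float) * 1000.0
        y = self._rho0 - np.asarray(y, dtype=float) * 1000.0
        rho = np.hypot(x, y)
        theta = np.arctan2(x, y)  # n > 0 for northern-hemisphere parallels
        lon = self.lon0 + np.degrees(theta / self._n)
        q = (self._C - (rho * self._n / WGS84_A) ** 2) / self._n
        qp = _q(np.array(1.0))
        ratio = np.clip(q / qp, -1.0, 1.0)
        phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
        for _ in range(30):
            sin_phi = np.sin(phi)
            cos_phi = np.cos(phi)
            with np.errstate(divide="ignore", invalid="ignore"):
                delta = (
                    (1.0 - _E2 * sin_phi**2) ** 2
                    / (2.0 * cos_phi)
                    * (
                        q / (1.0 - _E2)
                        - sin_phi / (1.0 - _E2 * sin_phi**2)
                        + (1.0 / (2.0 * _E))
                        * np.log((1.0 - _E * sin_phi) / (1.0 + _E * sin_phi))
                    )
                )
            delta = np.where(np.abs(ratio) >= 1.0 - 1e-12, 0.0, delta)
            phi = phi + delta
            if np.all(np.abs(delta) < 1e-13):
                break
        phi = np.where(np.abs(ratio) >= 1.0 - 1e-12, np.sign(q) * np.pi / 2.0, phi)
        return lon, np.degrees(phi)


def polygon_area_km2(geom, crs: str) -> float:
    """Planar area (km²) of a polygon already in an equal-area crs.

    Refuses geographic input: degree-coordinate "areas" are not areas.
    """
    if crs == GEOGRAPHIC_CRS or crs.upper().startswith("EPSG:4326"):
        raise MustProjectError("polygon must be projected to an equal-area crs first")
    return float(geom.area)
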