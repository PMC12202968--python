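"""Isoscape rescaling: from precipitation δ²H to expected fur δ²H.

Fur keratin records the hydrogen isotope composition of local precipitation
at the time it was grown, shifted and damped by diet and physiology.  The
standard correction is a linear rescaling fitted on known-origin samples:

    δ²H_fur = β₀ + β₁ · δ²H_precip + ε,   ε ~ N(0, residual_sd²)

Applied cellwise to a precipitation isoscape this yields the expected-fur
surface; the assignment error combines the calibration residual with the
mass-spectrometry analytical precision in quadrature.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import GeoPoint
from .projection import GEOGRAPHIC_CRS, AlbersEqualArea
from .raster import RasterGrid

__all__ = [
    "Isoscape",
    "RescalingFunction",
    "FurSample",
    "fit_rescaling",
    "expected_fur_surface",
    "assignment_sigma",
    "read_samples_csv",
    "write_samples_csv",
    "OriginsOffGridError",
    "DegenerateFitError",
]

_PLAUSIBLE = (-300.0, 50.0)  # ‰, VSMOW-SLAP


class OriginsOffGridError(ValueError):
    """Some true origins fall off the isoscape; offending ids are listed."""

    def __init__(self, ids):
        self.ids = list(ids)
        super().__init__(f"true origins off-grid or on nodata for samples: {self.ids}")


class DegenerateFitError(ValueError):
    """Rescaling regression is rank-deficient (constant precipitation values)."""


@dataclass
class Isoscape:
    """Precipitation δ²H surface (‰), optionally with a prediction-SE band."""

    grid: RasterGrid
    se_grid: RasterGrid | None = None

    def __post_init__(self) -> None:
        v = self.grid.values[~self.grid.nodata_mask]
        if v.size and (v.min() < _PLAUSIBLE[0] or v.max() > _PLAUSIBLE[1]):
            raise ValueError("isoscape values outside the plausible δ²H range [-300, 50]‰")
        if self.se_grid is not None:
            se = self.se_grid.values[~self.se_grid.nodata_mask]
            if se.size and se.min() < 0:
                raise ValueError("prediction SE must be non-negative")

    def value_at_point(self, p: GeoPoint) -> float:
        """Precipitation δ²H at the cell containing a geographic point."""
        if self.grid.crs == GEOGRAPHIC_CRS:
            return self.grid.value_at(p.lon, p.lat)
        alb = AlbersEqualArea.from_crs(self.grid.crs)
        x, y = alb.forward(p.lon, p.lat)
        return self.grid.value_at(x, y)


@dataclass(frozen=True)
class RescalingFunction:
    """Linear fur~precipitation calibration with its residual scatter (‰)."""

    intercept: float
    slope: float
    residual_sd: float
    n_calibration: int

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.n_calibration < 3:
            raise ValueError("calibration needs at least 3 samples")

    def __call__(self, precip):
        return self.intercept + self.slope * np.asarray(precip, dtype=float)


@dataclass(frozen=True)
class FurSample:
    """One fur δ²H measurement with its carcass-recovery site and date."""

    id: str
    d2h_fur: float
    site: GeoPoint
    date: _dt.date
    true_origin: GeoPoint | None = None

    def __post_init__(self) -> None:
        if not (_PLAUSIBLE[0] <= self.d2h_fur <= _PLAUSIBLE[1]):
            raise ValueError(f"{self.id}: δ²H_fur {self.d2h_fur}‰ outside plausible range")


def fit_rescaling(samples, isoscape: Isoscape) -> RescalingFunction:
    """OLS of fur δ²H on the isoscape value at each sample's true origin.

    The residual SD uses the n−2 denominator.  Samples whose true origin is
    off-grid (or on nodata) abort the fit with their ids listed.
    """
    samples = [s for s in samples if s.true_origin is not None]
    if len(samples) < 3:
        raise ValueError("need at least 3 known-origin samples")
    precip = np.array([isoscape.value_at_point(s.true_origin) for s in samples])
    off = [s.id for s, p in zip(samples, precip) if not np.isfinite(p)]
    if off:
        raise OriginsOffGridError(off)
    fur = np.array([s.d2h_fur for s in samples])
    if np.ptp(precip) == 0:
        raise DegenerateFitError("precipitation values constant across calibration origins")
    res = stats.linregress(precip, fur)
    resid = fur - (res.intercept + res.slope * precip)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (len(samples) - 2)))
    return RescalingFunction(float(res.intercept), float(res.slope), residual_sd, len(samples))


def expected_fur_surface(isoscape: Isoscape, f: RescalingFunction) -> RasterGrid:
    """Cellwise expected fur δ²H: μ_c = β₀ + β₁·precip_c, mask unchanged."""
    return isoscape.grid.copy_with(f(isoscape.grid.values))


def assignment_sigma(f: RescalingFunction, analytical_precision: float) -> float:
    """Quadrature combination of calibration residual and analytical precision."""
    if analytical_precision < 0:
        raise ValueError("analytical precision must be non-negative")
    return float(np.hypot(f.residual_sd, analytical_precision))


# --------------------------------------------------------------------- CSV I/O
def read_samples_csv(path: str | Path) -> list[FurSample]:
    """Columns: id, d2h_fur, lon, lat, date[, origin_lon, origin_lat]."""
    df = pd.read_csv(path)
    out = []
    has_origin = {"origin_lon", "origin_lat"}.issubset(df.columns)
    for rec in df.itertuples(index=False):
        origin = None
        if has_origin and np.isfinite(rec.origin_lon) and np.isfinite(rec.origin_lat):
            origin = GeoPoint(float(rec.origin_lon), float(rec.origin_lat))
        out.append(
            FurSample(
                str(rec.id),
                float(rec.d2h_fur),
                GeoPoint(float(rec.lon), float(rec.lat)),
                _dt.date.fromisoformat(str(rec.date)),
                origin,
            )
        )
    return out


def write_samples_csv(samples, path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "id": s.id,
                "d2h_fur": s.d2h_fur,
                "lon": s.site.lon,
                "lat": s.site.lat,
                "date": s.date.isoformat(),
                "origin_lon": s.true_origin.lon if s.true_origin else np.nan,
                "origin_lat": s.true_origin.lat if s.true_origin else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
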