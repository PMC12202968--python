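"""Probability-of-origin surfaces, quantile transform and threshold calibration.

For each fur sample the likelihood that its fur grew in cell c is a normal
density of the measured value around the cell's expected fur value,

    f_c ∝ exp(−(y − μ_c)² / 2σ²),

normalized to a probability mass over the assignment domain — the cells of
the (equal-area) expected-fur grid inside a buffered range mask built from
occurrence-county centroids.  Because probabilities are not comparable
across samples, each surface is transformed to its within-surface empirical
CDF ("quantile" surface); a single quantile threshold is then calibrated on
known-origin test samples so that the thresholded ("likely") regions contain
the true origin for a target fraction of the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .alphahull import InsufficientPointsError, alpha_shape
from .calibration import FurSample, OriginsOffGridError
from .geodesy import GeoPoint
from .projection import AlbersEqualArea
from .raster import RasterGrid

__all__ = [
    "RangeMask",
    "ProbabilitySurface",
    "QuantileSurface",
    "LikelyRegion",
    "build_range_mask",
    "assignment_surface",
    "quantile_transform",
    "calibrate_threshold",
    "likely_region",
    "cumulative_origin_proportion",
    "NoDomainError",
]


class NoDomainError(ValueError):
    """Assignment domain (mask ∩ grid) is empty."""


@dataclass
class RangeMask:
    """Buffered alpha hull of the known range, in the equal-area frame (km)."""

    polygon: Polygon
    alpha_km: float
    buffer_km: float
    source_points: np.ndarray  # (n, 2) projected centroids

    def contains_cells(self, grid: RasterGrid) -> np.ndarray:
        """Boolean grid: cell centers inside the mask polygon."""
        X, Y = grid.cell_centers()
        return shapely.contains_xy(self.polygon, X.ravel(), Y.ravel()).reshape(grid.shape)


@dataclass
class ProbabilitySurface:
    """Per-cell origin probability mass for one sample; sums to 1 in-domain."""

    grid: RasterGrid
    sample_id: str

    def __post_init__(self) -> None:
        p = self.grid.values[~self.grid.nodata_mask]
        if p.size == 0:
            raise NoDomainError(f"{self.sample_id}: empty assignment domain")
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: probabilities must be >=0 and sum to 1")


@dataclass
class QuantileSurface:
    """Within-surface ECDF of cell probabilities; the argmax cell is 1."""

    grid: RasterGrid
    sample_id: str


@dataclass
class LikelyRegion:
    """Cells whose quantile meets the calibrated threshold."""

    mask: np.ndarray
    threshold: float
    sample_id: str
    grid: RasterGrid  # geometry carrier (transform/crs of the quantile grid)

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"{self.sample_id}: likely region is empty")


def build_range_mask(
    centroids: list[GeoPoint],
    albers: AlbersEqualArea,
    alpha_km: float = 100.0,
    buffer_km: float = 250.0,
) -> RangeMask:
    """Alpha hull of the occurrence-county centroids, buffered outward.

    Falls back to the convex hull when the alpha shape at ``alpha_km`` is
    empty or disconnected.
    """
    if len(centroids) < 3:
        raise InsufficientPointsError("need at least 3 centroids")
    xy = np.array([albers.forward(c.lon, c.lat) for c in centroids])
    shape = alpha_shape(xy, alpha_km)
    if shape.is_empty or shape.geom_type != "Polygon":
        shape = alpha_shape(xy, np.inf)
    poly = shape.buffer(buffer_km)
    uncovered = ~shapely.covers(poly, shapely.points(xy))
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} centroid(s) fall outside the buffered range mask",
            stacklevel=2,
        )
    return RangeMask(poly, alpha_km, buffer_km, xy)


def assignment_surface(
    sample: FurSample,
    mu: RasterGrid,
    sigma: float,
    mask: RangeMask | None = None,
    se_grid: RasterGrid | None = None,
) -> ProbabilitySurface:
    """Normal-likelihood origin surface, normalized over the in-mask cells.

    ``mu`` must live in an equal-area crs so that per-cell normalization is a
    spatial probability mass.  With ``se_grid`` the scale becomes
    cell-specific: sqrt(σ² + se_c²).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    domain = ~mu.nodata_mask
    if mask is not None:
        domain &= mask.contains_cells(mu)
    if not domain.any():
        raise NoDomainError(f"{sample.id}: range mask does not intersect the grid")
    scale2 = sigma**2
    if se_grid is not None:
        scale2 = scale2 + se_grid.values**2
    logf = np.where(domain, -((sample.d2h_fur - mu.values) ** 2) / (2.0 * scale2), -np.inf)
    logf -= logf[domain].max()
    dens = np.where(domain, np.exp(logf), 0.0)
    p = dens / dens.sum()
    out = mu.copy_with(p)
    out.nodata_mask = ~domain
    return ProbabilitySurface(out, sample.id)


def quantile_transform(p: ProbabilitySurface) -> QuantileSurface:
    """Within-surface ECDF: q_c = #(cells with p <= p_c) / #cells.

    Ties share the maximal rank, so a uniform surface maps to all-ones and
    the argmax cell always has quantile 1.
    """
    domain = ~p.grid.nodata_mask
    vals = p.grid.values[domain]
    order = np.sort(vals)
    q = np.searchsorted(order, p.grid.values[domain], side="right") / vals.size
    out = p.grid.copy_with(np.zeros_like(p.grid.values))
    out.values[domain] = q
    return QuantileSurface(out, p.sample_id)


def _quantile_at_origin(q: QuantileSurface, origin: GeoPoint) -> float:
    grid = q.grid
    if grid.crs.startswith("albers"):
        alb = AlbersEqualArea.from_crs(grid.crs)
        x, y = alb.forward(origin.lon, origin.lat)
    else:
        x, y = origin.lon, origin.lat
    return grid.value_at(x, y)


def calibrate_threshold(
    test_samples: list[FurSample],
    surfaces: list[QuantileSurface],
    target_accuracy: float = 0.75,
) -> float:
    """Largest quantile threshold retaining >= target accuracy on the test set.

    Each test sample contributes the quantile value at its true origin; the
    threshold is the largest of those values θ with
    mean(q_i >= θ) >= target_accuracy — i.e. the inclusive lower-tail
    (1 − target) empirical quantile.  θ = min(q_i) is always admissible, so
    the search cannot fail.
    """
    if not test_samples:
        raise ValueError("empty test set")
    if len(test_samples) != len(surfaces):
        raise ValueError("test samples and surfaces must pair up")
    qs: list[float] = []
    off: list[str] = []
    for s, surf in zip(test_samples, surfaces):
        v = np.nan if s.true_origin is None else _quantile_at_origin(surf, s.true_origin)
        if not np.isfinite(v):
            off.append(s.id)
        else:
            qs.append(float(v))
    if off:
        raise OriginsOffGridError(off)
    q_arr = np.asarray(qs, dtype=float)
    ok = [th for th in np.unique(q_arr) if np.mean(q_arr >= th) >= target_accuracy]
    return float(max(ok))


def likely_region(q: QuantileSurface, threshold: float) -> LikelyRegion:
    """Cells with quantile >= threshold; always includes the argmax cell."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    domain = ~q.grid.nodata_mask
    mask = domain & (q.grid.values >= threshold)
    return LikelyRegion(mask, threshold, q.sample_id, q.grid)


def cumulative_origin_proportion(regions: list[LikelyRegion]) -> RasterGrid:
    """Cellwise fraction of samples whose likely region covers the cell."""
    if not regions:
        raise ValueError("need at least one likely region")
    first = regions[0].grid
    for r in regions[1:]:
        if r.grid.transform != first.transform or r.grid.crs != first.crs:
            raise ValueError("likely regions live on different grid geometries")
    stack = np.stack([r.mask for r in regions]).astype(float)
    out = first.copy_with(stack.mean(axis=0))
    out.nodata_mask = np.zeros(first.shape, dtype=bool)
    return out
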