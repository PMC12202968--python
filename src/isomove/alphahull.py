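"""Alpha shapes and dynamic alpha hulls for extent-of-occurrence polygons.

An alpha shape generalizes the convex hull: Delaunay triangles whose
circumradius exceeds the scale parameter alpha are discarded, letting the
outline follow concavities.  The "dynamic" hull searches a geometric ladder
of alpha values, starting from the convex-hull scale, for the smallest alpha
whose shape is still a single connected polygon containing at least the
required fraction of the points — the standard way occurrence records are
turned into seasonal range polygons.

All geometry here is planar; callers project points to the equal-area frame
(km) first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon

__all__ = ["alpha_shape", "dynamic_alpha_hull", "HullResult", "InsufficientPointsError"]


class InsufficientPointsError(ValueError):
    """Fewer than three non-collinear points — no polygon exists."""


def _check_points(xy: np.ndarray) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 3:
        raise InsufficientPointsError("need at least 3 points (x, y)")
    return xy


def alpha_shape(xy: np.ndarray, alpha: float):
    """Union of Delaunay triangles with circumradius <= alpha.

    ``alpha = inf`` returns the convex hull.  May be empty or a MultiPolygon
    for small alpha; callers decide how to treat those.
    """
    xy = _check_points(xy)
    if not np.isfinite(alpha):
        return MultiPoint(xy).convex_hull
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise InsufficientPointsError(f"degenerate point set: {exc}") from exc
    pts = xy[tri.simplices]  # (ntri, 3, 2)
    a = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    b = np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1)
    c = np.linalg.norm(pts[:, 2] - pts[:, 0], axis=1)
    # circumradius R = abc / 4K, K from the shoelace formula
    area2 = np.abs(
        (pts[:, 1, 0] - pts[:, 0, 0]) * (pts[:, 2, 1] - pts[:, 0, 1])
        - (pts[:, 2, 0] - pts[:, 0, 0]) * (pts[:, 1, 1] - pts[:, 0, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area2 > 0, a * b * c / (2.0 * area2), np.inf)
    keep = pts[circumradius <= alpha]
    if len(keep) == 0:
        return Polygon()
    return shapely.union_all([Polygon(t) for t in keep])


@dataclass
class HullResult:
    polygon: Polygon
    alpha_km: float
    inclusion: float
    used_fallback: bool
    n_points: int


def dynamic_alpha_hull(
    xy: np.ndarray,
    inclusion: float = 0.95,
    buffer_km: float = 50.0,
    land=None,
    ladder_steps: int = 9,
) -> HullResult:
    """Smallest-alpha single-polygon hull covering >= ``inclusion`` of points.

    The ladder is hull-scale × {1, 1/2, 1/4, ..., 1/256} (``ladder_steps``
    rungs); if no rung yields a single connected polygon meeting the
    inclusion floor, the convex hull is used with a warning.  The selected
    shape is buffered outward by ``buffer_km`` and, when a ``land`` polygon
    is supplied (same planar crs), clipped to it.
    """
    xy = _check_points(xy)
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise InsufficientPointsError("points are collinear")
    # convex-hull scale: diameter of the hull (max vertex-pair separation)
    v = np.asarray(hull.exterior.coords)
    scale = float(np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(-1)).max())

    pts = shapely.points(xy)
    best: tuple[float, Polygon, float] | None = None  # (alpha, shape, inclusion)
    for alpha in scale * 0.5 ** np.arange(ladder_steps):
        shape = alpha_shape(xy, alpha)
        if shape.geom_type != "Polygon" or shape.is_empty:
            continue
        frac = float(np.mean(shapely.covers(shape, pts)))
        if frac >= inclusion:
            best = (float(alpha), shape, frac)
    if best is None:
        warnings.warn(
            "no alpha on the ladder gave a single connected polygon meeting the "
            "inclusion floor; falling back to the convex hull",
            stacklevel=2,
        )
        frac = float(np.mean(shapely.covers(hull, pts)))
        best = (np.inf, hull, frac)
    alpha, shape, frac = best
    assert frac >= inclusion or best[0] == np.inf
    out = shape.buffer(buffer_km)
    if land is not None:
        out = out.intersection(land)
    return HullResult(out, alpha, frac, not np.isfinite(alpha), len(xy))
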