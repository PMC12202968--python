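"""Gridded surfaces: the raster container, text I/O and reprojection.

A :class:`RasterGrid` is a single-band, north-up, square-celled grid with an
explicit nodata mask and a crs string — either geographic degrees
(``EPSG:4326``) or an Albers equal-area frame in km (see
:mod:`isomove.projection`).  Grids are written as ESRI ASCII grids (a plain
text format readable by any GIS) with a small JSON sidecar carrying the crs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .projection import GEOGRAPHIC_CRS, AlbersEqualArea

__all__ = ["RasterGrid", "reproject_to_albers"]

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """Single-band raster: values, nodata mask, affine placement, crs.

    ``transform`` is ``(x0, y0, dx, dy)``: the coordinates of the top-left
    *corner* and the signed cell steps (dy < 0 for a north-up grid).  The
    center of cell (row i, col j) is ``(x0 + (j+0.5)dx, y0 + (i+0.5)dy)``.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    transform: tuple[float, float, float, float]
    crs: str = GEOGRAPHIC_CRS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if self.values.ndim != 2:
            raise ValueError("raster must be 2-D")
        x0, y0, dx, dy = self.transform
        if dx <= 0 or dy >= 0:
            raise ValueError("expect dx > 0 and dy < 0 (north-up)")
        if not np.isclose(dx, -dy):
            raise ValueError("cells must be square (dx == -dy)")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def resolution(self) -> float:
        """Cell edge length in crs units (km or degrees)."""
        return float(self.transform[2])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) 2-D arrays of cell-center coordinates in the raster crs."""
        x0, y0, dx, dy = self.transform
        nr, nc = self.shape
        xs = x0 + (np.arange(nc) + 0.5) * dx
        ys = y0 + (np.arange(nr) + 0.5) * dy
        return np.meshgrid(xs, ys)

    def centers_lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell centers in geographic degrees, whatever the raster crs."""
        X, Y = self.cell_centers()
        if self.crs == GEOGRAPHIC_CRS:
            return X, Y
        return AlbersEqualArea.from_crs(self.crs).inverse(X, Y)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell-center indices; halfway ties go to the smaller index.

        Coordinates are in the raster's own crs.  Returns (-1, -1) for points
        outside the grid extent.
        """
        x0, y0, dx, dy = self.transform
        fx = (np.asarray(x, dtype=float) - x0) / dx
        fy = (np.asarray(y, dtype=float) - y0) / dy
        col = np.floor(fx).astype(int)
        row = np.floor(fy).astype(int)
        # a point exactly on an interior cell edge is equidistant from the two
        # neighbouring centers; row-major tie-break = keep the smaller index
        col = np.where((fx == col) & (col > 0), col - 1, col)
        row = np.where((fy == row) & (row > 0), row - 1, row)
        nr, nc = self.shape
        inside = (col >= 0) & (col < nc) & (row >= 0) & (row < nr)
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def value_at(self, x, y) -> np.ndarray:
        """Values at the nearest cells; NaN off-grid or on nodata."""
        row, col = self.xy_to_rowcol(x, y)
        row_a, col_a = np.atleast_1d(row), np.atleast_1d(col)
        out = np.full(row_a.shape, np.nan, dtype=float)
        ok = row_a >= 0
        out[ok] = self.values[row_a[ok], col_a[ok]]
        nod = np.zeros_like(ok)
        nod[ok] = self.nodata_mask[row_a[ok], col_a[ok]]
        out[nod] = np.nan
        return float(out[0]) if np.ndim(row) == 0 else out

    def copy_with(self, values: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            self.values.copy() if values is None else np.asarray(values, dtype=float),
            self.nodata_mask.copy(),
            self.transform,
            self.crs,
        )

    # ------------------------------------------------------------------ text I/O
    def write_ascii(self, path: str | Path) -> None:
        """ESRI ASCII grid + ``<path>.crs.json`` sidecar; lossless round trip."""
        path = Path(path)
        x0, y0, dx, dy = self.transform
        nr, nc = self.shape
        vals = np.where(self.nodata_mask, _NODATA, self.values)
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {float(x0)!r}\nyllcorner {float(y0 + nr * dy)!r}\n"
            f"cellsize {float(dx)!r}\nNODATA_value {_NODATA!r}\n"
        )
        # repr of a Python float is the shortest digit string that round-trips,
        # so write-then-read preserves values bit-exactly
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
        path.write_text(header + body + "\n")
        Path(str(path) + ".crs.json").write_text(json.dumps({"crs": self.crs}))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        lines = path.read_text().splitlines()
        hdr = {}
        for line in lines[:6]:
            k, v = line.split()
            hdr[k.lower()] = float(v)
        nc, nr = int(hdr["ncols"]), int(hdr["nrows"])
        cell = hdr["cellsize"]
        vals = np.array([[float(t) for t in line.split()] for line in lines[6 : 6 + nr]])
        mask = vals == hdr["nodata_value"]
        vals = np.where(mask, np.nan, vals)
        transform = (hdr["xllcorner"], hdr["yllcorner"] + nr * cell, cell, -cell)
        sidecar = Path(str(path) + ".crs.json")
        crs = json.loads(sidecar.read_text())["crs"] if sidecar.exists() else GEOGRAPHIC_CRS
        grid = cls(np.where(mask, 0.0, vals), mask, transform, crs)
        return grid


def reproject_to_albers(
    src: RasterGrid, albers: AlbersEqualArea, resolution_km: float
) -> RasterGrid:
    """Nearest-neighbour resampling of a geographic grid onto an Albers grid.

    The output grid covers the projected footprint of the source cells; cells
    whose centers fall outside the source (or on source nodata) are nodata.
    """
    if src.crs != GEOGRAPHIC_CRS:
        raise ValueError("source raster must be geographic (EPSG:4326)")
    if resolution_km <= 0:
        raise ValueError("resolution must be positive")
    LON, LAT = src.cell_centers()
    X, Y = albers.forward(LON, LAT)
    half = resolution_km / 2.0
    x0 = float(X.min()) - half
    y1 = float(Y.max()) + half
    nc = int(np.ceil((X.max() + half - x0) / resolution_km))
    nr = int(np.ceil((y1 - (Y.min() - half)) / resolution_km))
    transform = (x0, y1, resolution_km, -resolution_km)
    out = RasterGrid(np.zeros((nr, nc)), np.zeros((nr, nc), dtype=bool), transform, albers.crs)
    CX, CY = out.cell_centers()
    lon, lat = albers.inverse(CX, CY)
    row, col = src.xy_to_rowcol(lon, lat)
    ok = row >= 0
    vals = np.zeros((nr, nc))
    mask = np.ones((nr, nc), dtype=bool)
    vals[ok] = src.values[row[ok], col[ok]]
    mask[ok] = src.nodata_mask[row[ok], col[ok]]
    out.values = vals
    out.nodata_mask = mask
    return out
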