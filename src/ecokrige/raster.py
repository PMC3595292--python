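"""Regular-grid raster type with ESRI ASCII grid I/O.

Conventions: planar meter coordinates, x east / y north.  ``data`` is stored
row-major north-to-south (row 0 is the northernmost row), matching the ESRI
ASCII layout.  The header is corner-registered (xllcorner/yllcorner) per the
format standard; sampling uses cell-center registration, so the center of the
lower-left cell is at (xll + cellsize/2, yll + cellsize/2).  Missing cells
are NaN in memory and -9999 on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

NODATA = -9999.0

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid", "NODATA"]


@dataclass
class RasterGrid:
    """2-D raster on a regular grid.

    Attributes
    ----------
    data : (nrows, ncols) float array, row 0 = north; NaN = nodata.
    xll, yll : coordinates of the lower-left *corner* of the grid (m).
    cellsize : cell edge length (m).
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise InvalidInputError("raster data must be a nonempty 2-D array")
        if self.cellsize <= 0:
            raise InvalidInputError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        """West-to-east cell-center x coordinates."""
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    @property
    def y_centers(self) -> np.ndarray:
        """North-to-south cell-center y coordinates (matches row order)."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) outer bounds."""
        return (
            self.xll,
            self.xll + self.ncols * self.cellsize,
            self.yll,
            self.yll + self.nrows * self.cellsize,
        )

    def grid_points(self) -> np.ndarray:
        """(nrows*ncols, 2) array of cell-center (x, y), row-major."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def like(self, data: np.ndarray) -> "RasterGrid":
        """New raster sharing this grid's georeferencing."""
        data = np.asarray(data, dtype=float).reshape(self.data.shape)
        return replace(self, data=data)

    def sample(self, xy: np.ndarray, method: str = "bilinear") -> np.ndarray:
        """Sample the raster at point coordinates.

        Bilinear interpolation between cell centers by default
        (``method="nearest"`` for nearest-neighbor).  Points outside the
        outer grid bounds return NaN with a logged warning; points between
        the bounds and the outermost cell centers use edge values.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if not np.isfinite(xy).all():
            raise InvalidInputError("sample coordinates must be finite")
        if method not in ("bilinear", "nearest"):
            raise InvalidInputError(f"unknown sampling method {method!r}")
        xmin, xmax, ymin, ymax = self.extent
        inside = (
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax) & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )
        n_out = int((~inside).sum())
        if n_out:
            logger.warning("%d sample point(s) outside raster extent -> nodata", n_out)
        # interpolator axes must be ascending: flip rows so y increases
        yc = self.y_centers[::-1]
        interp = RegularGridInterpolator(
            (yc, self.x_centers),
            self.data[::-1, :],
            method="linear" if method == "bilinear" else "nearest",
            bounds_error=False,
            fill_value=None,  # linear edge extrapolation for the half-cell rim
        )
        out = np.full(xy.shape[0], np.nan)
        if inside.any():
            pts = xy[inside][:, ::-1]  # (y, x) order
            # clamp the half-cell rim onto the outermost centers
            pts[:, 0] = np.clip(pts[:, 0], yc[0], yc[-1])
            pts[:, 1] = np.clip(pts[:, 1], self.x_centers[0], self.x_centers[-1])
            out[inside] = interp(pts)
        return out


def write_ascii_grid(grid: RasterGrid, path: str | Path, fmt: str = "%.6g") -> Path:
    """Write an ESRI ASCII grid (NODATA_value -9999)."""
    path = Path(path)
    data = np.where(np.isfinite(grid.data), grid.data, NODATA)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xll:.6f}\n"
        f"yllcorner {grid.yll:.6f}\n"
        f"cellsize {grid.cellsize:.6f}\n"
        f"NODATA_value {NODATA:.0f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise InvalidInputError(f"ASCII grid header missing {key}")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise InvalidInputError("ASCII grid body does not match header dimensions")
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    # support the cell-center registered header variant
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - header["cellsize"] / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - header["cellsize"] / 2)
    return RasterGrid(data=data, xll=xll, yll=yll, cellsize=header["cellsize"])
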