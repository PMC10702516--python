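"""Georeferenced rasters: affine cell<->coordinate mapping and text I/O.

Cells follow the common geo-raster convention: the origin is the *top-left*
corner of the grid, rows increase downward (negative y step), and each cell
is half-open — a point lying exactly on a shared edge belongs to the cell on
the left/top side of that edge.  Rasters are written as ESRI ASCII grids,
a plain-text interchange format readable by standard GIS tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeoTransform:
    """Affine map between cell indices and projected coordinates.

    ``x = x_origin + col * dx``, ``y = y_origin + row * dy`` give the
    top-left corner of cell (row, col); ``dy`` is negative (north-up).
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy >= 0:
            raise ValueError("expected dx > 0 and dy < 0 (north-up raster)")

    def rowcol(self, x, y):
        """Cell indices containing points (half-open, left/top inclusive)."""
        col = np.floor((np.asarray(x, float) - self.x_origin) / self.dx).astype(np.int64)
        row = np.floor((np.asarray(y, float) - self.y_origin) / self.dy).astype(np.int64)
        return row, col

    def cell_center(self, row, col):
        x = self.x_origin + (np.asarray(col) + 0.5) * self.dx
        y = self.y_origin + (np.asarray(row) + 0.5) * self.dy
        return x, y


@dataclass
class BandRaster:
    """Near-infrared and red reflectance bands with an optional cloud mask.

    ``cloud_mask`` is True where a cell was flagged (cloud / cloud shadow)
    and must be excluded from analysis.  Reflectances are nonnegative.
    """

    nir: np.ndarray
    red: np.ndarray
    transform: GeoTransform
    cloud_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nir = np.asarray(self.nir, float)
        self.red = np.asarray(self.red, float)
        if self.nir.shape != self.red.shape or self.nir.ndim != 2:
            raise ValueError("nir and red must be 2-D arrays of the same shape")
        if self.cloud_mask is not None:
            self.cloud_mask = np.asarray(self.cloud_mask, bool)
            if self.cloud_mask.shape != self.nir.shape:
                raise ValueError("cloud_mask shape must match the bands")
        if (self.nir < 0).any() or (self.red < 0).any():
            raise ValueError("reflectances must be nonnegative")

    @property
    def shape(self):
        return self.nir.shape


def write_ascii_grid(path, array: np.ndarray, transform: GeoTransform,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (requires square cells)."""
    array = np.asarray(array, float)
    if abs(transform.dx + transform.dy) > 1e-9:
        raise ValueError("ESRI ASCII grids require square cells (dx == -dy)")
    nrows, ncols = array.shape
    yll = transform.y_origin + nrows * transform.dy
    out = np.where(np.isfinite(array), array, nodata)
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {transform.x_origin!r}\nyllcorner {yll!r}\n"
        f"cellsize {transform.dx!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array with NaN nodata, GeoTransform)."""
    with open(path) as fh:
        hdr = {}
        while len(hdr) < 6:
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = data.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    data[data == hdr["nodata_value"]] = np.nan
    cell = hdr["cellsize"]
    gt = GeoTransform(hdr["xllcorner"], hdr["yllcorner"] + int(hdr["nrows"]) * cell,
                      cell, -cell)
    return data, gt


def write_mask_pgm(path, mask: np.ndarray) -> None:
    """Write a binary label mask as a plain (ASCII, P2) PGM image."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    with open(path, "w") as fh:
        fh.write(f"P2\n{mask.shape[1]} {mask.shape[0]}\n1\n")
        np.savetxt(fh, mask, fmt="%d")


def read_mask(path) -> np.ndarray:
    """Read a label mask image (any single-channel format imageio handles)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    mask = (img > 0).astype(np.uint8)
    return mask


def points_outside_warning(n_outside: int) -> None:
    if n_outside:
        warnings.warn(f"{n_outside} point(s) fall outside the raster extent; "
                      "their values are set to missing", stacklevel=3)
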