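"""Greenspace exposure metrics: GVI, NDVI, normalization, ratio, aggregation.

The Green View Index (GVI) of a location is the percentage of green pixels
pooled over the six street-view label masks taken at 60-degree intervals.
NDVI is the normalized difference (NIR - R)/(NIR + R) of near-infrared and
red reflectance bands, extracted at the exact point locations.  Both metrics
are min-max normalized over the study-domain units of a given spatial scale
and combined into the GVI:NDVI ratio, which contrasts street-level with
overhead greenery.  Exposure is analyzed at the point scale (nearest
greenspace point) and within buffer zones of radius 100-2000 m (unweighted
mean of in-radius points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from greensar.points import PointSet
from greensar.rasters import BandRaster, points_outside_warning

BUFFER_RADII_M = (0.0, 100.0, 300.0, 500.0, 1000.0, 2000.0)


def scale_label(radius_m: float) -> str:
    return "point" if radius_m == 0 else f"{radius_m:g} m"


def compute_gvi(masks) -> float:
    """Green View Index: pooled green-pixel percentage over six label masks.

    GVI = 100 * sum_i greenpixels_i / sum_i totalpixels_i, which for
    equal-size masks equals the mean of the per-image green fractions.
    """
    masks = [np.asarray(m) for m in masks]
    if len(masks) != 6:
        raise ValueError(f"expected exactly 6 masks, got {len(masks)}")
    green = total = 0
    for m in masks:
        if m.size == 0:
            raise ValueError("empty mask")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary (0=other, 1=green)")
        green += int(m.sum())
        total += m.size
    return 100.0 * green / total


def compute_ndvi(raster: BandRaster) -> np.ndarray:
    """Cellwise NDVI = (NIR - R)/(NIR + R); filtered cells become NaN.

    Cells flagged by the cloud mask, and degenerate cells where both bands
    are zero, are returned as missing rather than raising.
    """
    nir, red = raster.nir, raster.red
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    if raster.cloud_mask is not None:
        ndvi = np.where(raster.cloud_mask, np.nan, ndvi)
    return ndvi


def extract_ndvi_at_points(ndvi: np.ndarray, transform, points: PointSet) -> np.ndarray:
    """Value of the raster cell containing each point (half-open cells).

    Points outside the raster extent get NaN with a warning; missing cells
    propagate missing.
    """
    row, col = transform.rowcol(points.x, points.y)
    nrows, ncols = ndvi.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    points_outside_warning(int((~inside).sum()))
    out = np.full(points.n, np.nan)
    out[inside] = ndvi[row[inside], col[inside]]
    return out


def normalize_metric(values) -> np.ndarray:
    """Min-max rescale to [0, 1] over the study-domain units; NaNs pass through."""
    v = np.asarray(values, float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to normalize")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError("normalization undefined for constant input")
    return (v - lo) / (hi - lo)


def compute_ratio(gvi_norm, ndvi_norm) -> np.ndarray:
    """GVI_norm / NDVI_norm; units with zero (or missing) NDVI_norm are missing."""
    g = np.asarray(gvi_norm, float)
    d = np.asarray(ndvi_norm, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((d > 0) & np.isfinite(g), g / np.where(d > 0, d, 1.0), np.nan)
    return out


def aggregate_to_scale(points: PointSet, values, centers: PointSet,
                       radius_m: float) -> np.ndarray:
    """Aggregate per-point greenspace values to exposure units.

    radius 0 (point scale): each center takes the value of its nearest
    greenspace point, Euclidean distance, ties broken by lowest point id.
    radius > 0: unweighted mean of all values within the radius, boundary
    inclusive; centers with no in-radius point are missing.
    """
    if radius_m < 0:
        raise ValueError("radius must be nonnegative")
    values = np.asarray(values, float)
    tree = cKDTree(points.coords)
    if radius_m == 0:
        kq = min(points.n, 8)
        dist, idx = tree.query(centers.coords, k=kq)
        dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
        out = np.empty(centers.n)
        for i in range(centers.n):
            tied = np.isclose(dist[i], dist[i, 0], rtol=0, atol=1e-9)
            cand = idx[i, tied]
            out[i] = values[cand[np.argmin(points.ids[cand])]]
        return out
    neigh = tree.query_ball_point(centers.coords, r=radius_m)
    out = np.full(centers.n, np.nan)
    for i, nb in enumerate(neigh):
        if nb:
            vals = values[nb]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[i] = vals.mean()
    return out


def compute_iqr(values, interpolation: str = "linear") -> float:
    """Interquartile range Q3 - Q1 with interpolated sample quantiles."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 finite values for an IQR")
    q1, q3 = np.percentile(v, [25, 75], method=interpolation)
    return float(q3 - q1)


def build_greenspace_table(green_points: PointSet, gvi: np.ndarray,
                           ndvi: np.ndarray, centers: PointSet,
                           radii_m=BUFFER_RADII_M) -> pd.DataFrame:
    """Per-unit greenspace metrics at every spatial scale.

    Aggregates raw GVI and NDVI from the greenspace points to the exposure
    units (``centers``), then normalizes and forms the ratio within each
    scale, so each regression's metric set is self-consistent.
    Columns: unit_id, scale, gvi, ndvi, gvi_norm, ndvi_norm, ratio.
    """
    import warnings

    frames = []
    for r in radii_m:
        g = aggregate_to_scale(green_points, gvi, centers, r)
        d = aggregate_to_scale(green_points, ndvi, centers, r)
        try:
            gn = normalize_metric(g)
            dn = normalize_metric(d)
        except ValueError as exc:
            warnings.warn(f"scale {scale_label(r)}: {exc}; normalized metrics "
                          "set to missing", stacklevel=2)
            gn = np.full(centers.n, np.nan)
            dn = np.full(centers.n, np.nan)
        frames.append(pd.DataFrame({
            "unit_id": centers.ids, "scale": scale_label(r),
            "gvi": g, "ndvi": d, "gvi_norm": gn, "ndvi_norm": dn,
            "ratio": compute_ratio(gn, dn),
        }))
    return pd.concat(frames, ignore_index=True)
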