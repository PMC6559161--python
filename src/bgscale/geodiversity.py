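"""Elevation heterogeneity inside circular windows on a raster.

Heterogeneity is the sample standard deviation (n-1 denominator) of all
elevation cells whose centre lies within a given radius of a window
centre. Membership is inclusive on the boundary and evaluated at cell
centres, so the value set is independent of traversal order and nested
across radii. Distances are Euclidean in projected mode and haversine
(Earth radius 6,371 km) in geographic mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ElevationRaster

EARTH_RADIUS_KM = 6371.0


@dataclass
class CircularWindow:
    center: tuple[float, float]  # CRS units (m projected, deg lon/lat geographic)
    radius_km: float

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius_km}")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def window_values(raster: ElevationRaster, window: CircularWindow,
                  stride: int = 1) -> tuple[np.ndarray, bool]:
    """Elevations of all non-nodata cells with centre within the window radius.

    Returns ``(values, truncated)`` where ``truncated`` is True when the
    window circle extends past the raster edge or nodata cells fall inside
    it. ``stride`` subsamples every k-th cell in each direction (a speed
    knob for very large windows; default 1 = exact).

    Raises ValueError when the window centre lies outside the raster
    footprint (the window is then entirely undefined for this analysis).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    cx, cy = window.center
    xmin, ymin, xmax, ymax = raster.bounds()
    if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
        raise ValueError(
            f"window centre {window.center} outside raster footprint {raster.bounds()}")
    ox, oy = raster.origin
    cs = raster.cell_size

    if raster.crs_mode == "projected":
        r = window.radius_km * 1000.0
        j0 = int(np.floor((cx - r - ox) / cs))
        j1 = int(np.ceil((cx + r - ox) / cs))
        i0 = int(np.floor((oy - (cy + r)) / cs))
        i1 = int(np.ceil((oy - (cy - r)) / cs))
    else:
        # bounding box in degrees; lat degree ~ 111.19 km, lon shrinks by cos(lat)
        deg_lat = window.radius_km / (np.pi / 180.0 * EARTH_RADIUS_KM)
        coslat = max(np.cos(np.radians(cy)), 1e-6)
        deg_lon = deg_lat / coslat
        j0 = int(np.floor((cx - deg_lon - ox) / cs))
        j1 = int(np.ceil((cx + deg_lon - ox) / cs))
        i0 = int(np.floor((oy - (cy + deg_lat)) / cs))
        i1 = int(np.ceil((oy - (cy - deg_lat)) / cs))

    truncated = i0 < 0 or j0 < 0 or i1 > raster.ny or j1 > raster.nx
    i0c, i1c = max(i0, 0), min(i1, raster.ny)
    j0c, j1c = max(j0, 0), min(j1, raster.nx)
    if i0c >= i1c or j0c >= j1c:
        return np.empty(0), True

    ii = np.arange(i0c, i1c, stride)
    jj = np.arange(j0c, j1c, stride)
    ycent = oy - (ii + 0.5) * cs
    xcent = ox + (jj + 0.5) * cs
    if raster.crs_mode == "projected":
        d2 = (ycent[:, None] - cy) ** 2 + (xcent[None, :] - cx) ** 2
        inside = d2 <= (window.radius_km * 1000.0) ** 2 * (1 + 1e-12)
    else:
        dist = haversine_km(xcent[None, :], ycent[:, None], cx, cy)
        inside = dist <= window.radius_km * (1 + 1e-12)

    block = raster.values[np.ix_(ii, jj)]
    vals = block[inside]
    n_nodata = int(np.isnan(vals).sum())
    if n_nodata:
        truncated = True
        vals = vals[~np.isnan(vals)]
    return vals, truncated


def sd_elevation(values) -> float:
    """Sample SD (n-1) of a window's elevations; NaN when fewer than 2 values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1))
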