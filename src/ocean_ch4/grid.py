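"""Latitude/longitude grids, spherical cell areas, bathymetric region masks.

Grids follow a cell-center convention: a resolution-r grid over [lo, hi) has
centers lo + r/2, lo + 3r/2, ...  Longitudes are kept in [-180, 180).
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .constants import EARTH_RADIUS_M

#: Region-class codes, split by seafloor depth.
REGION_NEARSHORE = 0   # 0-50 m
REGION_SHELF = 1       # 50-200 m
REGION_SLOPE = 2       # 200-2000 m
REGION_OPEN = 3        # > 2000 m

REGION_NAMES = {
    REGION_NEARSHORE: "near-shore",
    REGION_SHELF: "outer shelf",
    REGION_SLOPE: "slope",
    REGION_OPEN: "open ocean",
}

#: Depth edges [m] separating the four region classes.
REGION_DEPTH_EDGES = (50.0, 200.0, 2000.0)


def cell_centers(lo: float, hi: float, resolution: float) -> np.ndarray:
    """Cell-center coordinates of a half-open [lo, hi) axis."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    n = (hi - lo) / resolution
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"resolution {resolution} does not divide extent [{lo}, {hi})"
        )
    n = int(round(n))
    return lo + resolution * (np.arange(n) + 0.5)


def cell_areas_m2(lat: np.ndarray, resolution: float) -> np.ndarray:
    """Exact spherical areas [m^2] of resolution x resolution cells.

    A = R^2 * dlon * (sin(lat_top) - sin(lat_bot)); returned per latitude row
    (identical across longitudes).
    """
    half = resolution / 2.0
    top = np.radians(np.clip(lat + half, -90.0, 90.0))
    bot = np.radians(np.clip(lat - half, -90.0, 90.0))
    dlon = np.radians(resolution)
    return EARTH_RADIUS_M**2 * dlon * (np.sin(top) - np.sin(bot))


def make_grid(
    resolution: float,
    lat_extent: tuple[float, float],
    lon_extent: tuple[float, float],
) -> xr.Dataset:
    """Build an empty grid skeleton with per-cell spherical areas."""
    lat = cell_centers(lat_extent[0], lat_extent[1], resolution)
    lon = cell_centers(lon_extent[0], lon_extent[1], resolution)
    lon = np.where(lon >= 180.0, lon - 360.0, lon)
    row_area = cell_areas_m2(lat, resolution)
    area = np.broadcast_to(row_area[:, None], (lat.size, lon.size)).copy()
    ds = xr.Dataset(
        {"cell_area": (("lat", "lon"), area, {"units": "m2"})},
        coords={"lat": lat, "lon": lon},
        attrs={"resolution_deg": resolution},
    )
    return ds


def region_mask(depth_m: np.ndarray) -> np.ndarray:
    """Classify cells into the four bathymetric region codes by depth [m]."""
    e1, e2, e3 = REGION_DEPTH_EDGES
    mask = np.full(depth_m.shape, REGION_OPEN, dtype=np.int8)
    mask[depth_m <= e3] = REGION_SLOPE
    mask[depth_m <= e2] = REGION_SHELF
    mask[depth_m <= e1] = REGION_NEARSHORE
    return mask


def hypsometry(depth_m: np.ndarray, cell_area: np.ndarray,
               bin_edges: np.ndarray) -> np.ndarray:
    """Ocean area [m^2] per depth bin (edges half-open [lo, hi))."""
    depth = np.asarray(depth_m).ravel()
    area = np.asarray(cell_area).ravel()
    idx = np.digitize(depth, bin_edges) - 1
    out = np.zeros(len(bin_edges) - 1)
    ok = (idx >= 0) & (idx < out.size)
    np.add.at(out, idx[ok], area[ok])
    return out


def bin_indices(lat: np.ndarray, lon: np.ndarray, grid: xr.Dataset):
    """Map point coordinates onto grid row/col indices (half-open cells)."""
    res = grid.attrs["resolution_deg"]
    glat = grid["lat"].values
    glon = grid["lon"].values
    i = np.floor((np.asarray(lat) - (glat[0] - res / 2)) / res).astype(int)
    j = np.floor((np.asarray(lon) - (glon[0] - res / 2)) / res).astype(int)
    ok = (i >= 0) & (i < glat.size) & (j >= 0) & (j < glon.size)
    return i, j, ok
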