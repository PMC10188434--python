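"""Gridded 3D concentration fields: construction, cell areas, layer slices.

A ``Field3D`` is represented as an :class:`xarray.Dataset` with coordinates
``lon`` (degrees East), ``lat`` (degrees North) and ``depth`` (metres,
positive down), a boolean ``water_mask(lat, lon)``, per-cell horizontal
areas ``cell_area_km2(lat, lon)`` computed on the sphere, and — once an
interpolator has run — the variable ``chla(depth, lat, lon)`` in ug/L with
NaN over land.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

EARTH_RADIUS_KM = 6371.0


def cell_areas_km2(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Spherical areas (km^2) of the lon/lat cells centred on the grid nodes.

    Each cell is the spherical quadrilateral spanning half a grid step in
    every direction: area = R^2 * dlambda * (sin(phi_n) - sin(phi_s)).
    Grids must be regularly spaced in each axis (single-node axes are not
    supported because the cell extent would be undefined).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(lon) < 2 or len(lat) < 2:
        raise ValueError("need at least 2 nodes per horizontal axis to define cell extents")
    dlon = np.deg2rad(np.diff(lon).mean())
    lat_edges = np.deg2rad(np.concatenate([
        [lat[0] - 0.5 * (lat[1] - lat[0])],
        0.5 * (lat[:-1] + lat[1:]),
        [lat[-1] + 0.5 * (lat[-1] - lat[-2])],
    ]))
    band = EARTH_RADIUS_KM**2 * dlon * (np.sin(lat_edges[1:]) - np.sin(lat_edges[:-1]))
    return np.repeat(band[:, None], len(lon), axis=1)


def make_grid(lon_range=(117.0, 123.0), lat_range=(37.0, 41.0),
              depths=(0.5, 10.0), resolution_deg: float = 0.05,
              water_mask: np.ndarray | None = None) -> xr.Dataset:
    """Build an empty 3D grid over a lon/lat box at the given depth layers.

    Nodes are *cell centres*: the first node sits half a step inside the
    box, so the cells tile the box exactly at every resolution and
    integrated totals converge under grid refinement.  ``water_mask`` is a
    (nlat, nlon) boolean array (True = water); by default the whole box is
    water, which matches the synthetic scenarios.
    """
    if resolution_deg <= 0:
        raise ValueError("resolution must be positive")
    half = 0.5 * resolution_deg
    lon = np.arange(lon_range[0] + half, lon_range[1], resolution_deg)
    lat = np.arange(lat_range[0] + half, lat_range[1], resolution_deg)
    depth = np.asarray(depths, dtype=float)
    if water_mask is None:
        water_mask = np.ones((len(lat), len(lon)), dtype=bool)
    water_mask = np.asarray(water_mask, dtype=bool)
    if water_mask.shape != (len(lat), len(lon)):
        raise ValueError(f"water_mask shape {water_mask.shape} != {(len(lat), len(lon))}")
    return xr.Dataset(
        {
            "water_mask": (("lat", "lon"), water_mask),
            "cell_area_km2": (("lat", "lon"), cell_areas_km2(lon, lat)),
        },
        coords={"lon": lon, "lat": lat, "depth": depth},
        attrs={"title": "chla3d gridded field"},
    )


def layer_slice(field: xr.Dataset, depth: float) -> xr.Dataset:
    """Extract one depth layer (concentrations + areas + mask) from a field.

    ``depth`` must match a grid layer exactly; returns a Dataset with
    ``chla(lat, lon)`` (NaN = missing/land), ``cell_area_km2`` and
    ``water_mask``.
    """
    depths = field["depth"].values
    hit = np.isclose(depths, depth)
    if not hit.any():
        raise KeyError(f"depth {depth} m not among grid layers {depths.tolist()}")
    sl = field.isel(depth=int(np.argmax(hit)))
    if "chla" not in sl:
        raise KeyError("field has no 'chla' variable; run an interpolator first")
    return sl
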