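"""Regional ecological indicators from gridded Chl-a fields.

Two ways of estimating the total chlorophyll-a standing amount of a
sub-region layer, plus the bloom-threshold exceedance area:

* **Integrated total** — sum of (interpolated cell concentration x cell
  area) over the region's water cells, units ug L^-1 km^2.  This is the
  areal integral of the reconstructed field for one layer.
* **Mean-method total** — the arithmetic mean of the in-region *station*
  concentrations multiplied by the region area.  With right-skewed data
  (a few very high coastal values) this overestimates, because the
  station mean is dominated by the coastal tail while the integral weights
  every cell equally.
* **High-Chl-a area** — summed area of cells whose concentration strictly
  exceeds a bloom threshold (default 10 ug/L).

Sub-region boundaries for the Bohai Sea (Bohai Bay BHB, Liaodong Bay LDB,
Laizhou Bay LZB, central Bohai Sea CBS) are not standardised; the module
ships illustrative rectangular defaults and accepts arbitrary polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, shape
from shapely.prepared import prep

from .config import BLOOM_THRESHOLD

__all__ = [
    "RegionMask",
    "total_chla_integrated",
    "total_chla_mean_method",
    "high_chla_area",
    "default_bohai_regions",
    "indicator_table",
]


@dataclass
class RegionMask:
    """A named horizontal sub-region: boolean mask over the grid's (lat, lon).

    ``area_km2`` is the sum of member cell areas, computed at construction.
    """

    name: str
    mask: np.ndarray
    cell_area_km2: np.ndarray
    area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.cell_area_km2 = np.asarray(self.cell_area_km2, dtype=float)
        if self.mask.shape != self.cell_area_km2.shape:
            raise ValueError("mask and cell-area shapes differ")
        if not self.mask.any():
            raise ValueError(f"region {self.name!r} is empty on this grid")
        self.area_km2 = float(self.cell_area_km2[self.mask].sum())

    @classmethod
    def from_bbox(cls, name: str, grid: xr.Dataset, lon_range, lat_range) -> "RegionMask":
        """Rectangular region: cells whose centre lies inside the lon/lat box."""
        lon = grid["lon"].values
        lat = grid["lat"].values
        inside = (
            (lat[:, None] >= lat_range[0]) & (lat[:, None] <= lat_range[1])
            & (lon[None, :] >= lon_range[0]) & (lon[None, :] <= lon_range[1])
        )
        return cls(name, inside & grid["water_mask"].values,
                   grid["cell_area_km2"].values)

    @classmethod
    def from_geojson(cls, name: str, grid: xr.Dataset, geometry: dict) -> "RegionMask":
        """Region from a GeoJSON geometry dict (cell-centre point-in-polygon)."""
        poly = prep(shape(geometry))
        lon = grid["lon"].values
        lat = grid["lat"].values
        inside = np.zeros((len(lat), len(lon)), dtype=bool)
        for i, la in enumerate(lat):
            for j, lo in enumerate(lon):
                inside[i, j] = poly.contains(Point(lo, la))
        return cls(name, inside & grid["water_mask"].values,
                   grid["cell_area_km2"].values)


def _layer_conc(layer: xr.Dataset) -> np.ndarray:
    if "chla" not in layer:
        raise KeyError("layer has no 'chla' variable")
    return layer["chla"].values


def total_chla_integrated(layer: xr.Dataset, region: RegionMask) -> dict:
    """Areal integral of the layer concentration over the region.

    Returns the total (ug L^-1 km^2) plus a coverage diagnostic: missing
    (NaN) cells contribute zero and are reported as ``n_missing``.
    """
    conc = _layer_conc(layer)
    if conc.shape != region.mask.shape:
        raise ValueError("layer and region are on different grids")
    m = region.mask
    if not m.any():
        raise ValueError(f"region {region.name!r} has no overlap with the layer grid")
    vals = conc[m]
    areas = region.cell_area_km2[m]
    missing = np.isnan(vals)
    total = float(np.nansum(vals * areas))
    return {"total": total, "n_cells": int(m.sum()), "n_missing": int(missing.sum()),
            "coverage": float(1.0 - missing.mean())}


def total_chla_mean_method(station_conc, region_area_km2: float) -> float:
    """Observation-mean total: mean station concentration x region area."""
    conc = np.asarray(station_conc, dtype=float)
    if conc.size == 0:
        raise ValueError("no stations fall inside the region")
    if region_area_km2 <= 0:
        raise ValueError("region area must be positive")
    return float(conc.mean() * region_area_km2)


def high_chla_area(layer: xr.Dataset, region: RegionMask,
                   threshold: float = BLOOM_THRESHOLD) -> float:
    """Summed area (km^2) of region cells strictly above the bloom threshold."""
    if threshold <= 0:
        raise ValueError("bloom threshold must be positive")
    conc = _layer_conc(layer)
    if conc.shape != region.mask.shape:
        raise ValueError("layer and region are on different grids")
    m = region.mask
    if not m.any():
        raise ValueError(f"region {region.name!r} has no overlap with the layer grid")
    over = m & (np.nan_to_num(conc, nan=-np.inf) > threshold)
    return float(region.cell_area_km2[over].sum())


#: Illustrative rectangular sub-region boxes (lon_range, lat_range), NOT an
#: authoritative delimitation of the bays; replace via GeoJSON for real use.
BOHAI_BBOXES = {
    "BHB": ((117.0, 118.6), (38.0, 39.2)),   # Bohai Bay (west)
    "LDB": ((120.0, 122.2), (39.8, 41.0)),   # Liaodong Bay (north)
    "LZB": ((118.8, 120.5), (37.0, 37.8)),   # Laizhou Bay (south)
    "CBS": ((118.7, 120.9), (38.1, 39.6)),   # central Bohai Sea
}


def default_bohai_regions(grid: xr.Dataset) -> list[RegionMask]:
    """The four illustrative sub-regions rasterised onto a grid (disjoint boxes)."""
    return [RegionMask.from_bbox(name, grid, lon_r, lat_r)
            for name, (lon_r, lat_r) in BOHAI_BBOXES.items()]


def indicator_table(field: xr.Dataset, regions, stations: pd.DataFrame | None = None,
                    layer_depths=(0.5, 10.0), threshold: float = BLOOM_THRESHOLD,
                    year=None, month=None) -> pd.DataFrame:
    """Tidy indicator table: one row per (layer, region).

    Columns: year, month, region, layer_m, total_integrated,
    total_mean_method (NaN when no station table or no in-region stations),
    bloom_area_km2, coverage.  Station membership for the mean method uses
    the same bounding logic as the region mask via nearest-cell lookup.
    """
    from .fields import layer_slice

    rows = []
    lon = field["lon"].values
    lat = field["lat"].values
    for dep in layer_depths:
        layer = layer_slice(field, dep)
        for region in regions:
            integ = total_chla_integrated(layer, region)
            mean_total = np.nan
            if stations is not None:
                st = stations[np.abs(stations["depth_m"] - dep) <= max(2.0, 0.3 * dep)]
                if len(st):
                    i = np.clip(np.searchsorted(lat, st["lat"]), 0, len(lat) - 1)
                    j = np.clip(np.searchsorted(lon, st["lon"]), 0, len(lon) - 1)
                    inside = region.mask[i, j]
                    if inside.any():
                        mean_total = total_chla_mean_method(
                            st["chl_ug_per_l"].to_numpy()[inside], region.area_km2)
            rows.append({
                "year": year, "month": month, "region": region.name, "layer_m": dep,
                "total_integrated": integ["total"],
                "total_mean_method": mean_total,
                "bloom_area_km2": high_chla_area(layer, region, threshold),
                "coverage": integ["coverage"],
            })
    return pd.DataFrame(rows)
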