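"""Readers and writers: station CSV tables and NetCDF gridded fields.

Station CSV dialect (header required, UTF-8): columns ``lon``, ``lat``,
``depth_m``, ``chl_ug_per_l`` plus optional ``layer``, ``year``, ``month``.
Invalid rows (unparseable numbers, out-of-range coordinates, nonpositive
concentrations) are rejected with their row number and a reason rather
than silently dropped.

Fields travel as NetCDF (classic format via the scipy backend) with
dimensions (depth, lat, lon), variables ``chla`` (ug/L), ``water_mask``
and ``cell_area_km2``, and global attributes recording the method, kernel,
epsilon, alpha and seed of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = ["StationTable", "read_stations", "write_stations",
           "read_field", "write_field", "StructuredError"]

REQUIRED_COLUMNS = ("lon", "lat", "depth_m", "chl_ug_per_l")
OPTIONAL_COLUMNS = ("layer", "year", "month")


class StructuredError(RuntimeError):
    """An error with a machine-readable code and a human message."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass
class StationTable:
    """Validated station records plus the provenance of any rejections."""

    stations: pd.DataFrame
    rejects: pd.DataFrame     # columns: row, reason
    source: str | None = None

    def __len__(self) -> int:
        return len(self.stations)


def _validate_rows(df: pd.DataFrame, detection_limit: float | None) -> tuple[pd.DataFrame, list]:
    rejects = []
    keep = np.ones(len(df), dtype=bool)
    num = {}
    for col in REQUIRED_COLUMNS:
        num[col] = pd.to_numeric(df[col], errors="coerce")
    for i in range(len(df)):
        row = i + 2  # header is line 1
        reasons = []
        for col in REQUIRED_COLUMNS:
            if np.isnan(num[col].iloc[i]):
                reasons.append(f"unparseable {col}")
        if not reasons:
            lon, lat = num["lon"].iloc[i], num["lat"].iloc[i]
            depth, chl = num["depth_m"].iloc[i], num["chl_ug_per_l"].iloc[i]
            if not (-180 <= lon <= 180):
                reasons.append("longitude out of range")
            if not (-90 < lat < 90):
                reasons.append("latitude out of range")
            if depth < 0:
                reasons.append("negative depth")
            if chl <= 0:
                if detection_limit is not None:
                    num["chl_ug_per_l"].iloc[i] = detection_limit
                else:
                    reasons.append("nonpositive concentration")
        if reasons:
            keep[i] = False
            rejects.append({"row": row, "reason": "; ".join(reasons)})
    out = df.loc[keep].copy()
    for col in REQUIRED_COLUMNS:
        out[col] = num[col].loc[keep].astype(float)
    return out.reset_index(drop=True), rejects


def read_stations(path: str | Path, detection_limit: float | None = None) -> StationTable:
    """Read and validate a station CSV.

    ``detection_limit`` (ug/L), when given, floors nonpositive
    concentrations instead of rejecting those rows (for censored data).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise StructuredError("bad-station-file", f"cannot read {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StructuredError("missing-columns",
                              f"{path} lacks required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise StructuredError("empty-table", f"{path} contains a header but no records")
    stations, rejects = _validate_rows(df, detection_limit)
    if len(stations) == 0:
        raise StructuredError("all-rows-rejected", f"no valid records in {path}")
    for rej in rejects:
        logger.warning("%s row %d rejected: %s", path.name, rej["row"], rej["reason"])
    return StationTable(stations=stations,
                        rejects=pd.DataFrame(rejects, columns=["row", "reason"]),
                        source=str(path))


def write_stations(stations: pd.DataFrame, path: str | Path) -> None:
    """Write a station table in the standard CSV dialect, full float precision."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in stations.columns]
    stations[cols].to_csv(path, index=False, float_format="%.17g")


def write_field(field: xr.Dataset, path: str | Path) -> None:
    """Write a gridded field to NetCDF (classic format, scipy backend)."""
    out = field.copy()
    # NetCDF3 has no boolean type
    out["water_mask"] = out["water_mask"].astype(np.int8)
    out.attrs = {k: (str(v) if not isinstance(v, (int, float, np.integer, np.floating))
                     else v) for k, v in field.attrs.items()}
    out.to_netcdf(path, engine="scipy")


def read_field(path: str | Path) -> xr.Dataset:
    """Read a field written by :func:`write_field`; validates required variables."""
    try:
        with xr.open_dataset(path, engine="scipy") as ds:
            field = ds.load()
    except (OSError, ValueError) as exc:
        raise StructuredError("bad-field-file", f"cannot read {path}: {exc}") from exc
    for var in ("water_mask", "cell_area_km2"):
        if var not in field:
            raise StructuredError("missing-variable",
                                  f"{path} lacks required variable {var!r}")
    field["water_mask"] = field["water_mask"].astype(bool)
    return field
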