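"""Coordinate transforms placing horizontal and vertical axes on comparable scales.

All interpolation in this package happens in *work coordinates*: the
horizontal position is Miller-projected (angles in radians, no Earth-radius
multiplier, so coordinates are order-1 and a degree of longitude is
~0.01745 work units), and depth is rescaled by a fixed divisor of 1000
(``z' = depth_m / 1000``).

This pair of conventions deliberately re-balances an anisotropic tracer
field: chlorophyll-a varies far faster with depth than horizontally, and
measuring horizontal separations in radians while dividing depth (metres)
by 1000 brings the change rates of all three axes to a comparable order of
magnitude before any Euclidean distance is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import VERTICAL_DIVISOR

__all__ = [
    "GeoPoint",
    "WorkPoint",
    "miller_project",
    "scale_depth",
    "to_work_point",
    "work_coords",
    "distance3",
]


@dataclass(frozen=True)
class GeoPoint:
    """A raw observation position: lon/lat in decimal degrees, depth in metres.

    Depth is positive downward with the surface at 0.
    """

    lon: float
    lat: float
    depth: float = 0.0

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 < self.lat < 90.0):
            raise ValueError(f"latitude {self.lat} outside (-90, 90)")
        if self.depth < 0:
            raise ValueError(f"depth {self.depth} must be >= 0 (positive downward)")


@dataclass(frozen=True)
class WorkPoint:
    """Transformed coordinates used by every interpolator.

    ``x``, ``y`` are Miller-projection abscissa/ordinate in Earth-radius
    (radian) units; ``z`` is depth divided by 1000.
    """

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def miller_project(lon, lat):
    """Miller cylindrical projection, spherical form, radian-scale output.

    x = lon_rad,  y = (5/4) * ln tan(pi/4 + 2*lat_rad/5).

    No Earth-radius multiplier is applied: coordinates stay order-1, which
    is the horizontal-scale convention the depth/1000 rescale is balanced
    against.  Accepts scalars or arrays; |lat| >= 90 is a domain error.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) >= 90.0):
        raise ValueError("latitude must satisfy |lat| < 90 degrees")
    lam = np.deg2rad(lon)
    phi = np.deg2rad(lat)
    x = lam
    y = 1.25 * np.log(np.tan(np.pi / 4.0 + 0.4 * phi))
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def scale_depth(depth_m, divisor: float = VERTICAL_DIVISOR):
    """Rescale depth (metres, positive down) to work units: z = depth/divisor.

    The default divisor of 1000 raises the weight of vertical variation so
    that vertical and horizontal change rates are comparable in distance
    computations.
    """
    depth_m = np.asarray(depth_m, dtype=float)
    if np.any(depth_m < 0):
        raise ValueError("depth must be >= 0 (positive downward)")
    z = depth_m / float(divisor)
    if z.ndim == 0:
        return float(z)
    return z


def to_work_point(p: GeoPoint) -> WorkPoint:
    """Compose the Miller projection and the depth rescale for one point."""
    x, y = miller_project(p.lon, p.lat)
    return WorkPoint(x=x, y=y, z=scale_depth(p.depth))


def work_coords(lon, lat, depth_m, divisor: float = VERTICAL_DIVISOR) -> np.ndarray:
    """Vectorised transform: (n,) lon/lat/depth arrays -> (n, 3) work coordinates."""
    x, y = miller_project(np.atleast_1d(lon), np.atleast_1d(lat))
    z = scale_depth(np.atleast_1d(depth_m), divisor)
    return np.column_stack([x, y, z])


def distance3(a, b) -> float:
    """Euclidean distance between two work points (or (3,) arrays)."""
    a = a.as_array() if isinstance(a, WorkPoint) else np.asarray(a, dtype=float)
    b = b.as_array() if isinstance(b, WorkPoint) else np.asarray(b, dtype=float)
    return float(np.sqrt(np.sum((a - b) ** 2)))
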