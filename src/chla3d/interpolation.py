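"""Scattered-data interpolators for 3D chlorophyll-a fields.

Two families operate on *work coordinates* (Miller-projected horizontal,
depth/1000 vertical; see :mod:`chla3d.geometry`):

* An augmented radial basis function interpolant with a degree-1 polynomial
  tail.  Concentrations are log10-transformed before fitting (Chl-a spans
  orders of magnitude) and back-transformed on output, so predictions are
  always positive.  The interpolant is

      Dhat'(q) = sum_i beta_i * phi(|q - p_i|) + l1 + l2*x + l3*y + l4*z

  with the coefficients solving the symmetric block system

      [[A, P], [P^T, 0]] [beta; lambda] = [D'; 0],

  A_ij = phi(d_ij), P = [1, x, y, z].  The orthogonality rows P^T beta = 0
  make the interpolant reproduce any field affine in (x, y, z) exactly.
  Three kernels: linear phi(d)=d, gaussian exp(-d^2/(2 eps^2)), and
  multiquadric sqrt(1 + d^2/eps^2), with shape constant eps = 0.1 in work
  units by default.

* Inverse distance weighting with power alpha = 3 by default, operating on
  raw concentrations (a log-space variant is available as a switch).  The
  zero-distance singularity is resolved by snapping to the observation when
  a query lies within 1e-12 work units of a station.

The model classes follow a fit/results split: construct the model from
coordinates and concentrations, call :meth:`fit`, and use the returned
results object to predict, inspect coefficients and diagnostics, or print a
summary.  Thin functional wrappers (``fit_rbf``, ``eval_rbf``, ``eval_idw``,
``kernel_eval``) cover the same surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
import xarray as xr

from .config import DEFAULT_ALPHA, DEFAULT_EPSILON
from .geometry import WorkPoint, work_coords

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "RBFInterpolator3D",
    "RBFResults",
    "IDW3D",
    "IDWResults",
    "fit_rbf",
    "eval_rbf",
    "fit_idw",
    "eval_idw",
    "merge_duplicate_stations",
    "interpolate_field",
]

#: queries closer than this (work units) to a station snap to its value (IDW).
IDW_SNAP_TOL = 1e-12

#: condition numbers above this trigger an ill-conditioning warning.
COND_WARN = 1e12

KERNELS = ("linear", "gaussian", "multiquadric")


@dataclass(frozen=True)
class KernelSpec:
    """A radial kernel: name in {linear, gaussian, multiquadric} plus shape eps.

    eps is ignored by the linear kernel and must be positive otherwise.
    """

    name: str = "linear"
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.name not in KERNELS:
            raise ValueError(f"unknown kernel {self.name!r}; expected one of {KERNELS}")
        if self.name != "linear" and self.epsilon <= 0:
            raise ValueError("epsilon must be positive for gaussian/multiquadric kernels")

    def __call__(self, d):
        return kernel_eval(self, d)


def kernel_eval(kernel: KernelSpec, d):
    """Evaluate phi(d) for a kernel at nonnegative distance(s) d."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if kernel.name == "linear":
        out = d
    elif kernel.name == "gaussian":
        out = np.exp(-0.5 * d**2 / kernel.epsilon**2)
    else:  # multiquadric
        out = np.sqrt(1.0 + d**2 / kernel.epsilon**2)
    return float(out) if out.ndim == 0 else out


def _as_points(points) -> np.ndarray:
    if isinstance(points, (list, tuple)) and points and isinstance(points[0], WorkPoint):
        return np.array([p.as_array() for p in points], dtype=float)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) work coordinates, got shape {pts.shape}")
    return pts


def merge_duplicate_stations(points, values, log_scale: bool) -> tuple[np.ndarray, np.ndarray]:
    """Average values observed at identical work coordinates.

    The augmented RBF system is singular under coordinate collisions, so
    duplicates are collapsed before fitting: averaged on the log10 scale for
    the RBF path (``log_scale=True``), on raw concentrations for IDW.  The
    number of merged records is logged.
    """
    pts = _as_points(points)
    vals = np.asarray(values, dtype=float)
    df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "v": vals})
    if log_scale:
        df["v"] = np.log10(df["v"])
    grouped = df.groupby(["x", "y", "z"], sort=False, as_index=False)["v"].mean()
    n_merged = len(df) - len(grouped)
    if n_merged:
        logger.warning("merged %d duplicate station(s) at identical coordinates", n_merged)
    out_vals = grouped["v"].to_numpy()
    if log_scale:
        out_vals = 10.0**out_vals
    return grouped[["x", "y", "z"]].to_numpy(), out_vals


class RBFInterpolator3D:
    """Augmented RBF model of log10 Chl-a over 3D work coordinates.

    Parameters
    ----------
    points : (n, 3) array or sequence of WorkPoint
        Station positions in work coordinates, pairwise distinct, n >= 5.
    conc : (n,) array
        Observed concentrations (ug/L), strictly positive.
    kernel : str or KernelSpec
        Radial kernel; default "linear".
    epsilon : float
        Shape constant when ``kernel`` is given by name.
    """

    def __init__(self, points, conc, kernel="linear", epsilon: float = DEFAULT_EPSILON):
        self.points = _as_points(points)
        self.conc = np.asarray(conc, dtype=float)
        self.kernel = kernel if isinstance(kernel, KernelSpec) else KernelSpec(kernel, epsilon)
        n = len(self.points)
        if len(self.conc) != n:
            raise ValueError("points and conc must have equal length")
        if n < 5:
            raise ValueError(f"RBF fit needs at least 5 stations, got {n}")
        if np.any(self.conc <= 0):
            raise ValueError(
                "nonpositive concentrations cannot be log-transformed; apply a "
                "detection-limit floor (config detection_limit) to censored data first"
            )
        # pairwise-distinct check
        if len(np.unique(self.points, axis=0)) != n:
            raise ValueError(
                "duplicate station coordinates make the interpolation system "
                "singular; merge them first (merge_duplicate_stations)"
            )

    @classmethod
    def from_stations(cls, stations: pd.DataFrame, kernel="linear",
                      epsilon: float = DEFAULT_EPSILON) -> "RBFInterpolator3D":
        """Build from a station table with lon/lat/depth_m/chl_ug_per_l columns."""
        pts = work_coords(stations["lon"], stations["lat"], stations["depth_m"])
        pts, vals = merge_duplicate_stations(pts, stations["chl_ug_per_l"], log_scale=True)
        return cls(pts, vals, kernel=kernel, epsilon=epsilon)

    def fit(self) -> "RBFResults":
        """Solve the augmented symmetric system for beta and lambda."""
        pts = self.points
        n = len(pts)
        d = scipy.spatial.distance.cdist(pts, pts)
        A = kernel_eval(self.kernel, d)
        P = np.column_stack([np.ones(n), pts])
        if np.linalg.matrix_rank(P) < 4:
            raise np.linalg.LinAlgError(
                "stations are coplanar in work coordinates (degenerate polynomial "
                "block); perturb positions or add out-of-plane stations"
            )
        K = np.zeros((n + 4, n + 4))
        K[:n, :n] = A
        K[:n, n:] = P
        K[n:, :n] = P.T
        rhs = np.concatenate([np.log10(self.conc), np.zeros(4)])
        cond = np.linalg.cond(K)
        if cond > COND_WARN:
            msg = f"RBF system condition number {cond:.3g} exceeds {COND_WARN:.0e}"
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        try:
            sol = scipy.linalg.solve(K, rhs, assume_a="sym")
        except np.linalg.LinAlgError:
            sol, *_ = scipy.linalg.lstsq(K, rhs)
            logger.warning("singular RBF system; used least-squares fallback")
        return RBFResults(model=self, beta=sol[:n], lam=sol[n:], condition_number=cond)


@dataclass
class RBFResults:
    """Fitted RBF interpolant: kernel weights beta, polynomial tail lambda."""

    model: RBFInterpolator3D
    beta: np.ndarray
    lam: np.ndarray
    condition_number: float

    @property
    def kernel(self) -> KernelSpec:
        return self.model.kernel

    @property
    def centers(self) -> np.ndarray:
        return self.model.points

    def predict_log10(self, q) -> np.ndarray:
        """Interpolated log10 concentration at query work coordinates (m, 3)."""
        q = np.atleast_2d(_as_points_query(q))
        d = scipy.spatial.distance.cdist(q, self.centers)
        phi = kernel_eval(self.kernel, d)
        tail = self.lam[0] + q @ self.lam[1:]
        return phi @ self.beta + tail

    def predict(self, q) -> np.ndarray:
        """Interpolated concentration (ug/L, always > 0) at query points.

        The exponent is clamped to +/-300 so that wild extrapolations from
        ill-conditioned kernels stay positive finite instead of under- or
        overflowing to 0/inf.
        """
        return 10.0 ** np.clip(self.predict_log10(q), -300.0, 300.0)

    def summary(self) -> str:
        m = self.model
        ortho = float(np.max(np.abs(m.points.T @ self.beta))) if len(self.beta) else 0.0
        ortho = max(ortho, abs(float(np.sum(self.beta))))
        lines = [
            "RBF interpolation results",
            "=" * 46,
            f"kernel:            {self.kernel.name} (epsilon={self.kernel.epsilon:g})",
            f"n stations:        {len(m.points)}",
            f"conc range (ug/L): [{m.conc.min():.4g}, {m.conc.max():.4g}]",
            f"lambda (1,x,y,z):  {np.array2string(self.lam, precision=4)}",
            f"max |P^T beta|:    {ortho:.3g}",
            f"condition number:  {self.condition_number:.3g}",
        ]
        return "\n".join(lines)


class IDW3D:
    """Inverse-distance-weighting model over 3D work coordinates.

    Operates on raw concentrations by default (``log_transform=True``
    switches to log10 space with back-transform on output).
    """

    def __init__(self, points, values, alpha: float = DEFAULT_ALPHA,
                 log_transform: bool = False):
        self.points = _as_points(points)
        self.values = np.asarray(values, dtype=float)
        if len(self.points) != len(self.values):
            raise ValueError("points and values must have equal length")
        if len(self.points) == 0:
            raise ValueError("IDW needs at least one station")
        if np.any(self.values <= 0):
            raise ValueError("concentrations must be strictly positive")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = float(alpha)
        self.log_transform = bool(log_transform)

    @classmethod
    def from_stations(cls, stations: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                      log_transform: bool = False) -> "IDW3D":
        pts = work_coords(stations["lon"], stations["lat"], stations["depth_m"])
        pts, vals = merge_duplicate_stations(pts, stations["chl_ug_per_l"],
                                             log_scale=log_transform)
        return cls(pts, vals, alpha=alpha, log_transform=log_transform)

    def fit(self) -> "IDWResults":
        return IDWResults(model=self)


@dataclass
class IDWResults:
    """Fitted IDW predictor (fitting is storage; prediction does the work)."""

    model: IDW3D

    def predict(self, q) -> np.ndarray:
        m = self.model
        q = np.atleast_2d(_as_points_query(q))
        d = scipy.spatial.distance.cdist(q, m.points)
        vals = np.log10(m.values) if m.log_transform else m.values
        with np.errstate(divide="ignore"):
            w = d ** (-m.alpha)
        out = np.empty(len(q))
        snap = d < IDW_SNAP_TOL
        has_snap = snap.any(axis=1)
        finite_rows = ~has_snap
        if finite_rows.any():
            wr = w[finite_rows]
            out[finite_rows] = (wr * vals).sum(axis=1) / wr.sum(axis=1)
        if has_snap.any():
            idx = np.argmax(snap[has_snap], axis=1)
            out[has_snap] = vals[idx]
        return 10.0**out if m.log_transform else out

    def summary(self) -> str:
        m = self.model
        return "\n".join([
            "IDW interpolation results",
            "=" * 46,
            f"n stations:        {len(m.points)}",
            f"alpha:             {m.alpha:g}",
            f"log-space weights: {m.log_transform}",
            f"value range:       [{m.values.min():.4g}, {m.values.max():.4g}] ug/L",
        ])


def _as_points_query(q) -> np.ndarray:
    if isinstance(q, WorkPoint):
        return q.as_array()
    if isinstance(q, (list, tuple)) and q and isinstance(q[0], WorkPoint):
        return np.array([p.as_array() for p in q])
    return np.asarray(q, dtype=float)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_rbf(points, conc, kernel="linear", epsilon: float = DEFAULT_EPSILON) -> RBFResults:
    """Fit the augmented RBF system; see :class:`RBFInterpolator3D`."""
    return RBFInterpolator3D(points, conc, kernel=kernel, epsilon=epsilon).fit()


def eval_rbf(results: RBFResults, q):
    """Evaluate a fitted RBF at query point(s); returns concentrations in ug/L."""
    out = results.predict(q)
    return float(out[0]) if np.ndim(_as_points_query(q)) == 1 else out


def fit_idw(points, values, alpha: float = DEFAULT_ALPHA,
            log_transform: bool = False) -> IDWResults:
    return IDW3D(points, values, alpha=alpha, log_transform=log_transform).fit()


def eval_idw(results: IDWResults, q):
    """Evaluate a fitted IDW predictor at query point(s)."""
    out = results.predict(q)
    return float(out[0]) if np.ndim(_as_points_query(q)) == 1 else out


# ---------------------------------------------------------------------------
# Method registry and gridded evaluation
# ---------------------------------------------------------------------------

def make_interpolator(method: str, stations: pd.DataFrame, *,
                      epsilon: float = DEFAULT_EPSILON, alpha: float = DEFAULT_ALPHA,
                      idw_log_transform: bool = False):
    """Fit the named method on a station table; returns a results object."""
    if method.startswith("rbf-"):
        kernel = method.removeprefix("rbf-")
        return RBFInterpolator3D.from_stations(stations, kernel=kernel, epsilon=epsilon).fit()
    if method == "idw":
        return IDW3D.from_stations(stations, alpha=alpha, log_transform=idw_log_transform).fit()
    raise ValueError(f"unknown interpolation method {method!r}")


def interpolate_field(stations: pd.DataFrame, grid: xr.Dataset, method: str = "rbf-linear",
                      *, epsilon: float = DEFAULT_EPSILON, alpha: float = DEFAULT_ALPHA,
                      idw_log_transform: bool = False, fitted=None) -> xr.Dataset:
    """Fill every water cell of a 3D grid with interpolated concentrations.

    ``grid`` must carry lon/lat/depth coordinates plus ``water_mask`` and
    ``cell_area_km2`` (see :func:`chla3d.fields.make_grid`).  Land cells stay
    NaN.  A pre-fitted results object may be passed via ``fitted`` (the
    plugin hook: anything with a ``predict((m, 3) work coords) -> (m,)``
    contract works, e.g. a third-party kriging baseline).
    """
    if fitted is None:
        fitted = make_interpolator(method, stations, epsilon=epsilon, alpha=alpha,
                                   idw_log_transform=idw_log_transform)
    lon = grid["lon"].values
    lat = grid["lat"].values
    depth = grid["depth"].values
    mask = grid["water_mask"].values.astype(bool)
    glon, glat = np.meshgrid(lon, lat)  # (nlat, nlon)
    wet = mask.ravel()
    out = np.full((len(depth), len(lat), len(lon)), np.nan)
    for k, dep in enumerate(depth):
        pts = work_coords(glon.ravel()[wet], glat.ravel()[wet],
                          np.full(wet.sum(), float(dep)))
        layer = np.full(len(lat) * len(lon), np.nan)
        layer[wet] = fitted.predict(pts)
        out[k] = layer.reshape(len(lat), len(lon))
    field = grid.copy()
    field["chla"] = (("depth", "lat", "lon"), out)
    field["chla"].attrs.update(units="ug/L", long_name="chlorophyll-a concentration")
    field.attrs.update(
        method=method, epsilon=float(epsilon), alpha=float(alpha),
        idw_log_transform=int(idw_log_transform),
        kernel=method.removeprefix("rbf-") if method.startswith("rbf-") else "",
        transform="miller+depth/1000, log10 conc (rbf)",
    )
    return field
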