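"""Statistical downscaling of coarse temperature forecasts.

Seasonal forecast systems issue 2-m temperature on a coarse (~0.25 deg)
grid at 6-h steps; phenology models need daily means on the fine
observational grid.  The bridge is built in two steps:

1. **Regridding** — inverse-distance-weighted (IDW) interpolation from
   the coarse cell centers to each fine cell.
2. **Asynchronous regression** — for each fine cell and calendar month,
   an affine map ``fine = a * coarse + b`` fit on *rank-paired* (sorted)
   values from an archive of past coarse and fine temperatures.  Pairing
   by empirical quantile rather than timestamp makes the fit robust to
   the fact that a free-running climate model is not synchronized with
   observed weather; only the distributions need to correspond.

The fitted model stores exactly two parameters (slope, intercept) per
fine cell per calendar month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.spatial import cKDTree

from .models import make_cube

__all__ = [
    "DownscalingModel",
    "aggregate_to_daily",
    "interpolate_idw",
    "idw_weights",
    "fit_asynchronous_regression",
    "build_downscaling_model",
    "apply_downscaling",
    "month_of_day",
]

IDW_NEIGHBORS = 4
IDW_POWER = 2.0
MIN_MONTH_SAMPLES = 30
STEPS_PER_DAY = 4  # 6-h forecast time step


class DegenerateDataError(ValueError):
    """Regression input has zero variance or too few samples."""


def month_of_day(days: np.ndarray, reference_year: int) -> np.ndarray:
    """Calendar month (1-12) of extended day indices.

    Day 1 is 1 January of ``reference_year``; day 0 is 31 December of
    the prior year, negative days reach back further.
    """
    origin = np.datetime64(f"{reference_year - 1}-12-31")
    dates = origin + np.asarray(days, dtype=int).astype("timedelta64[D]")
    return dates.astype("datetime64[M]").astype(int) % 12 + 1


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def aggregate_to_daily(cube: xr.DataArray) -> xr.DataArray:
    """Collapse a 6-h temperature cube to daily means.

    The time coordinate must be extended-day values at uniform 0.25-day
    steps aligned to day boundaries; each day's value is the mean of its
    four 6-h values and a trailing partial day is dropped.
    """
    cube = cube.transpose("lat", "lon", "time")
    t = np.asarray(cube["time"].values, dtype=float)
    steps = np.diff(t)
    if len(t) < STEPS_PER_DAY or not np.allclose(steps, 1.0 / STEPS_PER_DAY):
        raise ValueError("expected uniform 6-h time steps")
    if not np.isclose(t[0] % 1.0, 0.0):
        raise ValueError("6-h steps must be aligned to day boundaries")
    n_days = len(t) // STEPS_PER_DAY
    vals = cube.values[:, :, : n_days * STEPS_PER_DAY]
    daily = vals.reshape(vals.shape[0], vals.shape[1], n_days, STEPS_PER_DAY).mean(axis=3)
    out = make_cube(daily, cube["lat"].values, cube["lon"].values, int(round(t[0])))
    out.attrs.update({k: v for k, v in cube.attrs.items() if k != "units"})
    out.attrs["units"] = "degC"
    return out


def idw_weights(
    coarse_lats: np.ndarray,
    coarse_lons: np.ndarray,
    fine_points: np.ndarray,
    k: int = IDW_NEIGHBORS,
    p: float = IDW_POWER,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and normalized weights of the k nearest coarse centers.

    ``fine_points`` is (n, 2) of (lat, lon).  A fine point coinciding
    with a coarse center gets that center's full weight; points outside
    the coarse grid's bounding box fall back to the single nearest
    center.  Returns ``(indices, weights)`` of shape (n, k) indexing the
    flattened (lat-major) coarse grid.
    """
    glat, glon = np.meshgrid(coarse_lats, coarse_lons, indexing="ij")
    centers = np.column_stack([glat.ravel(), glon.ravel()])
    if centers.shape[0] == 0:
        raise ValueError("empty coarse field")
    k = min(k, centers.shape[0])
    tree = cKDTree(centers)
    dist, idx = tree.query(fine_points, k=k)
    dist = np.atleast_2d(dist.astype(float))
    idx = np.atleast_2d(idx)
    with np.errstate(divide="ignore"):
        w = dist ** (-p)
    exact = dist < 1e-9
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)
    outside = (
        (fine_points[:, 0] < coarse_lats.min()) | (fine_points[:, 0] > coarse_lats.max())
        | (fine_points[:, 1] < coarse_lons.min()) | (fine_points[:, 1] > coarse_lons.max())
    )
    if outside.any():  # nearest-neighbour fallback beyond the grid edge
        nn = np.zeros_like(w[outside])
        nn[:, 0] = 1.0
        w[outside] = nn
    w = w / w.sum(axis=1, keepdims=True)
    return idx, w


def interpolate_idw(
    coarse: xr.DataArray,
    fine_lats: np.ndarray,
    fine_lons: np.ndarray,
    k: int = IDW_NEIGHBORS,
    p: float = IDW_POWER,
) -> xr.DataArray:
    """IDW-regrid a coarse field (or cube) onto a fine lat/lon grid.

    ``coarse`` has dims (lat, lon) or (lat, lon, time); the output has
    the fine axes in place of the coarse ones.
    """
    fine_lats = np.asarray(fine_lats, dtype=float)
    fine_lons = np.asarray(fine_lons, dtype=float)
    fl, fn = np.meshgrid(fine_lats, fine_lons, indexing="ij")
    pts = np.column_stack([fl.ravel(), fn.ravel()])
    idx, w = idw_weights(coarse["lat"].values, coarse["lon"].values, pts, k=k, p=p)

    has_time = "time" in coarse.dims
    arr = coarse.transpose("lat", "lon", "time").values if has_time else coarse.values[..., None]
    flat = arr.reshape(-1, arr.shape[2])  # (ncoarse, nt)
    fine_vals = np.einsum("nk,nkt->nt", w, flat[idx])
    shape = (len(fine_lats), len(fine_lons), arr.shape[2])
    fine_vals = fine_vals.reshape(shape)
    if not has_time:
        return xr.DataArray(
            fine_vals[:, :, 0], dims=("lat", "lon"),
            coords={"lat": fine_lats, "lon": fine_lons}, name=coarse.name,
        )
    out = xr.DataArray(
        fine_vals, dims=("lat", "lon", "time"),
        coords={"lat": fine_lats, "lon": fine_lons, "time": coarse["time"].values},
        name=coarse.name, attrs=dict(coarse.attrs),
    )
    return out


# ---------------------------------------------------------------------------
# Asynchronous regression
# ---------------------------------------------------------------------------

def _rank_pair(coarse: np.ndarray, fine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort both samples and equalize lengths via the empirical quantile
    function of the longer one."""
    x = np.sort(np.asarray(coarse, dtype=float))
    y = np.sort(np.asarray(fine, dtype=float))
    if len(x) == len(y):
        return x, y
    n = min(len(x), len(y))
    q = np.linspace(0.0, 1.0, n)
    if len(x) > n:
        x = np.quantile(x, q)
    else:
        y = np.quantile(y, q)
    return x, y


def fit_asynchronous_regression(
    coarse_series: np.ndarray, fine_series: np.ndarray
) -> tuple[float, float]:
    """Slope and intercept of sorted fine values on sorted coarse values.

    Both inputs are daily means already restricted to one calendar month
    across the archive years.  Values are paired by rank (empirical
    quantile), never by timestamp, so any permutation of either series
    in time yields the same fit.

    Raises
    ------
    DegenerateDataError
        Fewer than 30 values in either series, or zero variance in the
        sorted coarse values.
    """
    coarse_series = np.asarray(coarse_series, dtype=float)
    fine_series = np.asarray(fine_series, dtype=float)
    if len(coarse_series) < MIN_MONTH_SAMPLES or len(fine_series) < MIN_MONTH_SAMPLES:
        raise DegenerateDataError(
            f"need >= {MIN_MONTH_SAMPLES} values per month, got "
            f"{len(coarse_series)}/{len(fine_series)}"
        )
    x, y = _rank_pair(coarse_series, fine_series)
    if np.ptp(x) < 1e-12:
        raise DegenerateDataError("zero variance in sorted coarse values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


@dataclass
class DownscalingModel:
    """Per-cell, per-calendar-month affine maps from coarse to fine.

    ``slope`` and ``intercept`` have shape (n_lat, n_lon, 12); NaN marks
    cell/months that could not be fit (insufficient or degenerate data).
    """

    lats: np.ndarray
    lons: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        expected = (len(self.lats), len(self.lons), 12)
        if self.slope.shape != expected or self.intercept.shape != expected:
            raise ValueError(f"slope/intercept must have shape {expected}")


def build_downscaling_model(
    coarse_archive: xr.DataArray,
    fine_archive: xr.DataArray,
    reference_year: int,
    k: int = IDW_NEIGHBORS,
    p: float = IDW_POWER,
) -> DownscalingModel:
    """Fit the asynchronous-regression downscaling model from archives.

    Both archives are daily cubes on a shared extended-day time axis
    (``reference_year`` anchors day 1 to 1 January of that year, so
    multi-year archives simply continue past day 365).  The coarse
    archive is IDW-interpolated to each fine cell, then for each cell
    and calendar month an affine map is fit on rank-paired values.
    Cell/months with fewer than 30 common days or degenerate coarse
    values get NaN parameters rather than fabricated ones.
    """
    fine_archive = fine_archive.transpose("lat", "lon", "time")
    tc = np.asarray(coarse_archive["time"].values, dtype=int)
    tf = np.asarray(fine_archive["time"].values, dtype=int)
    common, ic, if_ = np.intersect1d(tc, tf, return_indices=True)
    if len(common) < 365:
        raise ValueError("archives must overlap at least one full year")
    coarse_at_fine = interpolate_idw(
        coarse_archive.isel(time=ic), fine_archive["lat"].values,
        fine_archive["lon"].values, k=k, p=p,
    ).values  # (nlat, nlon, nt)
    fine_vals = fine_archive.isel(time=if_).values
    months = month_of_day(common, reference_year)

    nlat, nlon = fine_vals.shape[:2]
    slope = np.full((nlat, nlon, 12), np.nan)
    intercept = np.full((nlat, nlon, 12), np.nan)
    for m in range(1, 13):
        sel = months == m
        if sel.sum() < MIN_MONTH_SAMPLES:
            continue
        x = np.sort(coarse_at_fine[:, :, sel], axis=2)
        y = np.sort(fine_vals[:, :, sel], axis=2)
        xm = x.mean(axis=2, keepdims=True)
        ym = y.mean(axis=2, keepdims=True)
        varx = ((x - xm) ** 2).sum(axis=2)
        cov = ((x - xm) * (y - ym)).sum(axis=2)
        ok = varx > 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(ok, cov / varx, np.nan)
        slope[:, :, m - 1] = s
        intercept[:, :, m - 1] = np.where(ok, ym[:, :, 0] - s * xm[:, :, 0], np.nan)
    return DownscalingModel(
        fine_archive["lat"].values, fine_archive["lon"].values, slope, intercept,
        attrs={"reference_year": reference_year, "idw_k": k, "idw_power": p},
    )


def apply_downscaling(
    forecast: xr.DataArray,
    model: DownscalingModel,
    reference_year: int,
    k: int = IDW_NEIGHBORS,
    p: float = IDW_POWER,
) -> xr.DataArray:
    """Downscale a 6-h coarse forecast cube to the fine grid.

    Aggregates to daily means, IDW-regrids to the model's fine grid,
    then applies each cell's calendar-month affine map.  Cells with
    missing parameters for a needed month come back NaN.
    """
    daily = aggregate_to_daily(forecast)
    fine = interpolate_idw(daily, model.lats, model.lons, k=k, p=p)
    days = np.asarray(fine["time"].values, dtype=int)
    months = month_of_day(days, reference_year) - 1  # 0-based
    a = model.slope[:, :, months]  # (nlat, nlon, nt)
    b = model.intercept[:, :, months]
    out = fine.copy(data=a * fine.values + b)
    out.attrs["reference_year"] = reference_year
    return out
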