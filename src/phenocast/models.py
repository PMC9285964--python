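"""Process-based thermal-forcing phenology models.

The model family predicts the day a phenological event (budburst, open
flowers, ripe fruit, fall colors) occurs by accumulating daily thermal
forcing from a start day ``t1`` until a species/phenophase-specific
requirement is met.  All models are driven solely by the 24-h daily mean
temperature.

Time is handled on an *extended day axis*: day 1 is 1 January of the
target year, day 0 is 31 December of the prior year, and 1 November of
the prior year is day -60 (non-leap counting).  This makes arithmetic
across the year boundary unambiguous; a predicted "Julian day" is simply
the extended index when it is >= 1.

Four families are implemented:

``thermal_time``
    Growing-degree-day model: daily unit ``max(0, T - T_base)``
    accumulated from ``t1``; event when the sum reaches ``F_star``.
``alternating``
    Chill/forcing trade-off: growing degree days above 5 deg C are
    accumulated from ``t1`` while cold days (``T < chill_threshold``)
    are counted; the forcing requirement on day *d* is
    ``a + b * exp(c * NCD_d)`` with ``NCD_d`` the chill-day count.
``uniforc``
    Sigmoidal forcing response ``1 / (1 + exp(b_sig * (T - c_sig)))``
    with ``b_sig < 0`` so forcing increases with temperature;
    accumulated from ``t1`` to requirement ``F_star``.
``linear``
    Regression of the event day on the mean temperature over a fixed
    window: ``day = round(beta0 + beta1 * mean(T))``.

These four forms are the canonical suite of the published
thermal-forcing model literature; see ``docs/methods.md`` for why this
particular suite was chosen and how it may differ from other
implementations of the same family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "NO_EVENT",
    "STATUS_EVENT",
    "STATUS_NO_EVENT",
    "STATUS_MISSING",
    "FAMILIES",
    "DailyTemperatureSeries",
    "ModelParameters",
    "forcing_units",
    "predict_event_day",
    "predict_matrix",
    "predict_grid",
    "make_cube",
]

#: Sentinel returned when accumulated forcing never reaches the requirement
#: within the supplied temperature series.
NO_EVENT: int = -32768

STATUS_EVENT = 0  #: an event day was predicted
STATUS_NO_EVENT = 1  #: forcing requirement never met within the series
STATUS_MISSING = 2  #: temperature record too gappy to predict

FAMILIES = ("thermal_time", "alternating", "uniforc", "linear")

#: Parameter names per family (chill_threshold has a literature-standard
#: default and is typically fixed rather than fitted).
FAMILY_PARAMS = {
    "thermal_time": ("t1", "T_base", "F_star"),
    "alternating": ("t1", "a", "b", "c", "chill_threshold"),
    "uniforc": ("t1", "b_sig", "c_sig", "F_star"),
    "linear": ("beta0", "beta1", "window_start", "window_end"),
}

#: GDD base used by the alternating model's forcing sum (deg C).
ALTERNATING_FORCING_BASE = 5.0

_TEMP_MIN, _TEMP_MAX = -60.0, 60.0
_MAX_GAP_DAYS = 3  # longest run of missing days filled by interpolation


class CoverageError(ValueError):
    """The temperature series does not span the model's required window."""


@dataclass
class DailyTemperatureSeries:
    """Contiguous daily mean temperatures on the extended day axis.

    Parameters
    ----------
    start_day
        Extended day index of the first value (day 1 = 1 Jan of the
        target year; prior-year days are <= 0).
    values
        Daily mean temperature in deg C, one value per consecutive day.
        Missing days are ``NaN``.
    """

    start_day: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < _TEMP_MIN or finite.max() > _TEMP_MAX):
            raise ValueError(
                f"temperatures outside plausible range [{_TEMP_MIN}, {_TEMP_MAX}] deg C"
            )

    @property
    def end_day(self) -> int:
        """Extended day index of the last value (inclusive)."""
        return self.start_day + len(self.values) - 1

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.start_day, self.start_day + len(self.values))

    def value_on(self, day: int) -> float:
        if not self.start_day <= day <= self.end_day:
            raise CoverageError(f"day {day} outside series [{self.start_day}, {self.end_day}]")
        return float(self.values[day - self.start_day])


@dataclass
class ModelParameters:
    """A fitted phenology model: family name plus its named parameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        self.params = dict(self.params)
        if self.family == "alternating":
            self.params.setdefault("chill_threshold", 5.0)
        missing = [p for p in FAMILY_PARAMS[self.family] if p not in self.params]
        if missing:
            raise ValueError(f"{self.family} parameters missing {missing}")
        for name, value in self.params.items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is not finite: {value}")
        if "F_star" in self.params and self.params["F_star"] <= 0:
            raise ValueError("F_star must be positive")
        if self.family == "linear" and not self.params["window_start"] < self.params["window_end"]:
            raise ValueError("linear model requires window_start < window_end")


def _fill_short_gaps(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate runs of <= _MAX_GAP_DAYS missing days.

    Returns the filled array and a boolean mask of days that remain
    missing (gap too long, or at the ends of the record).
    """
    vals = np.array(values, dtype=float, copy=True)
    isnan = ~np.isfinite(vals)
    if not isnan.any():
        return vals, isnan
    n = len(vals)
    idx = np.arange(n)
    still_missing = isnan.copy()
    # walk runs of NaN; interior runs of length <= limit get interpolated
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        run = j - i
        if 0 < i and j < n and run <= _MAX_GAP_DAYS:
            vals[i:j] = np.interp(idx[i:j], [i - 1, j], [vals[i - 1], vals[j]])
            still_missing[i:j] = False
        i = j
    return vals, still_missing


def _daily_units(T: np.ndarray, days: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Per-day forcing units for a forcing family, zero before t1.

    ``T`` has shape (n, n_days); ``days`` is the shared extended day axis.
    """
    p = params.params
    t1 = int(round(p["t1"]))
    if params.family == "thermal_time":
        units = np.maximum(T - p["T_base"], 0.0)
    elif params.family == "uniforc":
        units = 1.0 / (1.0 + np.exp(p["b_sig"] * (T - p["c_sig"])))
    elif params.family == "alternating":
        units = np.maximum(T - ALTERNATING_FORCING_BASE, 0.0)
    else:
        raise ValueError(f"{params.family} is not a forcing family")
    units = np.where(days[np.newaxis, :] >= t1, units, 0.0)
    return units


def forcing_units(series: DailyTemperatureSeries, params: ModelParameters) -> np.ndarray:
    """Cumulative forcing per day of ``series`` under a forcing model.

    The returned array has one entry per day of the series; entries
    before ``t1`` are 0 and the sequence is non-decreasing.
    """
    if params.family == "linear":
        raise ValueError("linear model does not accumulate forcing")
    t1 = int(round(params.params["t1"]))
    if series.start_day > t1:
        raise CoverageError(
            f"series starts at day {series.start_day}, after model start day t1={t1}"
        )
    vals, missing = _fill_short_gaps(series.values)
    if missing[series.days >= t1].any():
        raise CoverageError("temperature record has unfillable gaps after t1")
    units = _daily_units(vals[np.newaxis, :], series.days, params)
    return np.cumsum(units[0])


def _predict_rows(
    T: np.ndarray, days: np.ndarray, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized event-day prediction for row-stacked series.

    Parameters
    ----------
    T
        (n, n_days) matrix of daily mean temperatures; rows may contain
        NaN only where the caller has decided the row is unusable.
    days
        Shared extended day axis, length n_days.

    Returns
    -------
    day, status
        ``day`` is int (NO_EVENT where no event), ``status`` one of the
        STATUS_* codes, both of shape (n,).
    """
    n = T.shape[0]
    p = params.params
    row_missing = ~np.isfinite(T).all(axis=1)
    Tf = np.where(np.isfinite(T), T, 0.0)  # placeholder; masked rows flagged below

    if params.family == "linear":
        w0, w1 = int(round(p["window_start"])), int(round(p["window_end"]))
        if days[0] > w0 or days[-1] < w1:
            raise CoverageError(
                f"series [{days[0]}, {days[-1]}] does not cover linear window [{w0}, {w1}]"
            )
        sel = (days >= w0) & (days <= w1)
        row_missing = ~np.isfinite(T[:, sel]).all(axis=1)
        mean_T = Tf[:, sel].mean(axis=1)
        day = np.rint(p["beta0"] + p["beta1"] * mean_T).astype(int)
        inside = (day >= days[0]) & (day <= days[-1])
        status = np.where(inside, STATUS_EVENT, STATUS_NO_EVENT)
        day = np.where(inside, day, NO_EVENT)
    else:
        t1 = int(round(p["t1"]))
        if days[0] > t1:
            raise CoverageError(
                f"series starts at day {days[0]}, after model start day t1={t1}"
            )
        units = _daily_units(Tf, days, params)
        cum = np.cumsum(units, axis=1)
        if params.family == "alternating":
            chill = (Tf < p["chill_threshold"]) & (days[np.newaxis, :] >= t1)
            ncd = np.cumsum(chill, axis=1)
            req = p["a"] + p["b"] * np.exp(p["c"] * ncd)
        else:
            req = np.broadcast_to(p["F_star"], cum.shape)
        met = cum >= req
        hit = met.any(axis=1)
        first = np.argmax(met, axis=1)
        day = np.where(hit, days[first], NO_EVENT)
        status = np.where(hit, STATUS_EVENT, STATUS_NO_EVENT)

    day = np.where(row_missing, NO_EVENT, day)
    status = np.where(row_missing, STATUS_MISSING, status)
    return day.astype(int), status.astype(np.int8)


def predict_event_day(series: DailyTemperatureSeries, params: ModelParameters) -> int:
    """Predict the event day for a single site.

    Returns the extended day index of the first day on which the
    accumulated forcing meets the requirement (or the rounded linear
    prediction), or :data:`NO_EVENT` if the requirement is never met
    within the series.

    Raises
    ------
    CoverageError
        If the series does not span the model's accumulation window, or
        the record has gaps longer than 3 days inside it.
    """
    vals, missing = _fill_short_gaps(series.values)
    if missing.any():
        # only fatal if the gap intersects the model's active window
        days = series.days
        if params.family == "linear":
            w0 = int(round(params.params["window_start"]))
            w1 = int(round(params.params["window_end"]))
            active = (days >= w0) & (days <= w1)
        else:
            active = days >= int(round(params.params["t1"]))
        if missing[active].any():
            raise CoverageError("temperature record has unfillable gaps in the model window")
    day, status = _predict_rows(vals[np.newaxis, :], series.days, params)
    return int(day[0])


def predict_matrix(
    T: np.ndarray, start_day: int, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Predict event days for row-stacked daily series sharing one axis.

    ``T`` is (n, n_days) with NaN marking missing days.  Gaps of up to
    3 consecutive days are linearly interpolated per row; rows with
    longer gaps in the model's active window come back with
    STATUS_MISSING.  Returns ``(day, status)`` arrays of length n.
    """
    T = np.asarray(T, dtype=float)
    days = np.arange(start_day, start_day + T.shape[1])
    if not np.isnan(T).any():  # fast path: complete records
        return _predict_rows(T, days, params)
    filled = np.empty_like(T)
    missing = np.empty(T.shape, dtype=bool)
    for i in range(T.shape[0]):
        filled[i], missing[i] = _fill_short_gaps(T[i])
    if params.family == "linear":
        w0 = int(round(params.params["window_start"]))
        w1 = int(round(params.params["window_end"]))
        active = (days >= w0) & (days <= w1)
    else:
        active = days >= int(round(params.params["t1"]))
    bad = missing[:, active].any(axis=1)
    filled[bad] = np.nan
    return _predict_rows(filled, days, params)


def predict_grid(cube: xr.DataArray, params: ModelParameters) -> xr.Dataset:
    """Apply one phenology model to every cell of a temperature cube.

    Parameters
    ----------
    cube
        ``(lat, lon, time)`` daily mean temperature in deg C with an
        integer extended-day ``time`` coordinate (see :func:`make_cube`).
    params
        The model to apply.

    Returns
    -------
    xarray.Dataset with variables ``day`` (float; NaN where no event or
    missing) and ``status`` (int8 STATUS_* codes), dims ``(lat, lon)``.
    """
    if set(cube.dims) != {"lat", "lon", "time"}:
        raise ValueError(f"cube must have dims (lat, lon, time), got {cube.dims}")
    cube = cube.transpose("lat", "lon", "time")
    time = cube["time"].values.astype(int)
    if not np.all(np.diff(time) == 1):
        raise ValueError("cube time axis must be strictly consecutive daily steps")
    nlat, nlon = cube.sizes["lat"], cube.sizes["lon"]
    T = cube.values.reshape(nlat * nlon, len(time))
    day, status = predict_matrix(T, int(time[0]), params)
    day_f = np.where(status == STATUS_EVENT, day, np.nan).astype(float)
    return xr.Dataset(
        {
            "day": (("lat", "lon"), day_f.reshape(nlat, nlon)),
            "status": (("lat", "lon"), status.reshape(nlat, nlon)),
        },
        coords={"lat": cube["lat"], "lon": cube["lon"]},
    )


def make_cube(
    values: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    start_day: int,
    reference_year: int | None = None,
) -> xr.DataArray:
    """Assemble a ``(lat, lon, time)`` daily temperature cube.

    ``time`` is the integer extended day axis starting at ``start_day``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be (lat, lon, time)")
    time = np.arange(start_day, start_day + values.shape[2])
    da = xr.DataArray(
        values,
        dims=("lat", "lon", "time"),
        coords={"lat": np.asarray(lats, float), "lon": np.asarray(lons, float), "time": time},
        name="tmean",
        attrs={"units": "degC", "long_name": "daily mean 2-m air temperature"},
    )
    if reference_year is not None:
        da.attrs["reference_year"] = int(reference_year)
    return da
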