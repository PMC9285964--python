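"""Gridded ensemble forecasts of phenological event dates.

A forecast run splices observed temperatures (up to the issue date)
with several downscaled climate-forecast members (after it), runs the
species' phenology ensemble over each spliced member cube, and
summarizes the member predictions per grid cell into a point estimate,
a spread (SD), a 95% prediction interval, and an anomaly against the
latitude baseline.  The member spread is the only uncertainty source
carried: the process models themselves are deterministic, so all
forecast uncertainty here reflects uncertainty in the temperature
forecast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .fitting import LatitudeBaseline, StackedEnsemble, predict_ensemble_grid
from .models import STATUS_EVENT, STATUS_MISSING, STATUS_NO_EVENT

__all__ = [
    "ClimateMember",
    "ForecastProduct",
    "assemble_member",
    "run_member_forecasts",
    "summarize_members",
    "compute_anomaly",
    "apply_range_mask",
]

#: z-score of the 95% two-sided normal interval.
Z95 = 1.96

#: Fraction of members that must predict an event at a cell for the cell
#: to be summarized (over the responding subset); 3 of 5 at the nominal
#: member count.
MIN_RESPONDER_FRACTION = 0.6


class SpliceGapError(ValueError):
    """Observed and forecast cubes do not meet without a gap."""


@dataclass
class ClimateMember:
    """One spliced daily temperature member for a forecast run.

    ``cube`` spans 1 November of the prior year (extended day -60, by
    default) through the forecast horizon; ``provenance`` marks each day
    as ``"observed"`` or ``"forecast"``.
    """

    member_id: int
    issue_day: int
    cube: xr.DataArray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.cube["time"].values, dtype=int)
        if not np.all(np.diff(t) == 1):
            raise ValueError("member time axis must be strictly daily with no gaps")
        if len(self.provenance) != len(t):
            raise ValueError("provenance must have one entry per day")


def assemble_member(
    observed: xr.DataArray,
    downscaled: xr.DataArray,
    issue_day: int,
    member_id: int = 0,
) -> ClimateMember:
    """Splice observed and forecast temperature cubes at the issue date.

    Days before the forecast's first day come from ``observed``; every
    day the forecast covers comes from the forecast (forecast wins on
    overlap).  Raises :class:`SpliceGapError` naming the missing days if
    the two records do not meet.
    """
    t_obs = np.asarray(observed["time"].values, dtype=int)
    t_fc = np.asarray(downscaled["time"].values, dtype=int)
    fc_start = int(t_fc[0])
    if t_obs[-1] < fc_start - 1:
        missing = list(range(int(t_obs[-1]) + 1, fc_start))
        raise SpliceGapError(f"gap between observed and forecast temperatures: days {missing}")
    keep_obs = t_obs < fc_start
    obs_part = observed.isel(time=keep_obs)
    cube = xr.concat(
        [obs_part.transpose("lat", "lon", "time"), downscaled.transpose("lat", "lon", "time")],
        dim="time",
    )
    cube.name = "tmean"
    provenance = np.array(
        ["observed"] * int(keep_obs.sum()) + ["forecast"] * len(t_fc), dtype=object
    )
    return ClimateMember(member_id=member_id, issue_day=issue_day, cube=cube,
                         provenance=provenance)


def run_member_forecasts(
    members: list[ClimateMember], ensemble: StackedEnsemble
) -> list[xr.Dataset]:
    """Run the phenology ensemble over every climate member's cube.

    Returns one ``(day, status)`` grid per member, in member order.
    """
    if not members:
        raise ValueError("need at least one climate member")
    return [predict_ensemble_grid(m.cube, ensemble) for m in members]


def summarize_members(
    member_grids: list[xr.Dataset],
    day_span: tuple[int, int] | None = None,
) -> xr.Dataset:
    """Collapse per-member predicted-day grids to forecast statistics.

    Per cell: the point estimate is the member mean rounded to the
    nearest day, the uncertainty is the sample (n-1) standard deviation
    across members, and the 95% prediction interval is the normal
    approximation ``point +/- 1.96 * sd``, clipped to ``day_span`` when
    given.  Cells where fewer than 60% of members (3 of 5 nominal)
    predict an event are missing; cells summarized over a strict subset
    of members are flagged ``partial``.
    """
    day = np.stack([g["day"].values for g in member_grids])  # (m, lat, lon)
    status = np.stack([g["status"].values for g in member_grids])
    n_members = day.shape[0]
    responding = status == STATUS_EVENT
    n_resp = responding.sum(axis=0)
    need = max(2, int(np.ceil(MIN_RESPONDER_FRACTION * n_members))) if n_members > 1 else 1
    ok = n_resp >= need

    masked = np.where(responding, day, np.nan)
    with np.errstate(invalid="ignore"):
        point = np.rint(np.nanmean(masked, axis=0))
        if n_members >= 2:
            sd = np.nanstd(masked, axis=0, ddof=1)
        else:
            sd = np.zeros_like(point)
    sd = np.where(n_resp >= 2, sd, 0.0)
    point = np.where(ok, point, np.nan)
    sd = np.where(ok, sd, np.nan)
    pi_low = point - Z95 * sd
    pi_high = point + Z95 * sd
    if day_span is not None:
        pi_low = np.clip(pi_low, day_span[0], day_span[1])
        pi_high = np.clip(pi_high, day_span[0], day_span[1])
    partial = ok & (n_resp < n_members)
    return xr.Dataset(
        {
            "point_estimate": (("lat", "lon"), point),
            "sd": (("lat", "lon"), sd),
            "pi_low": (("lat", "lon"), pi_low),
            "pi_high": (("lat", "lon"), pi_high),
            "n_responding": (("lat", "lon"), n_resp.astype(np.int8)),
            "partial": (("lat", "lon"), partial),
        },
        coords={"lat": member_grids[0]["lat"], "lon": member_grids[0]["lon"]},
    )


def compute_anomaly(
    point_estimate: xr.DataArray, baseline: LatitudeBaseline
) -> xr.DataArray:
    """Predicted day minus the latitude-corrected long-term average.

    Negative anomalies mean the event is forecast earlier than average.
    """
    lat = point_estimate["lat"].values
    expected = baseline.expected_day(lat)[:, None]
    out = point_estimate - expected
    out.name = "anomaly"
    out.attrs["units"] = "days"
    return out


@dataclass
class ForecastProduct:
    """One species x phenophase gridded forecast for one issue date.

    ``data`` holds ``prediction, sd, pi_low, pi_high, anomaly`` on
    (lat, lon); every variable is NaN outside the species range mask.
    """

    species: str
    phenophase: str
    issue_day: int
    data: xr.Dataset
    range_mask: np.ndarray
    attrs: dict = field(default_factory=dict)


def apply_range_mask(
    summary: xr.Dataset,
    anomaly: xr.DataArray,
    mask: np.ndarray,
    species: str,
    phenophase: str,
    issue_day: int,
) -> ForecastProduct:
    """Crop forecast grids to the species range and package the product.

    Cells outside ``mask`` are set missing in every variable.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != summary["point_estimate"].shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grids {summary['point_estimate'].shape}"
        )
    keep = xr.DataArray(mask, dims=("lat", "lon"),
                        coords={"lat": summary["lat"], "lon": summary["lon"]})
    data = xr.Dataset(
        {
            "prediction": summary["point_estimate"].where(keep),
            "sd": summary["sd"].where(keep),
            "pi_low": summary["pi_low"].where(keep),
            "pi_high": summary["pi_high"].where(keep),
            "anomaly": anomaly.where(keep),
        }
    )
    return ForecastProduct(
        species=species, phenophase=phenophase, issue_day=issue_day,
        data=data, range_mask=mask,
    )


def plot_product(product: ForecastProduct, path, variable: str = "prediction"):
    """Render one product variable as a static map (requires matplotlib).

    A minimal dissemination helper: predicted day, uncertainty, or
    anomaly on the lat/lon grid with a colorbar, saved to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    da = product.data[variable]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.pcolormesh(da["lon"].values, da["lat"].values, da.values, shading="nearest")
    fig.colorbar(im, ax=ax, label=f"{variable} (days)")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(f"{product.species} {product.phenophase} — issued day {product.issue_day}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
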