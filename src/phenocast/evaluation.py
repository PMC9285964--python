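"""Forecast verification against subsequently observed events.

Once events are observed, each forecast issue date can be scored: the
root-mean-square error of the predicted dates, the mean signed error
(positive = predicted later than observed), and the mean forecast SD
(the uncertainty the system advertised).  Plotting RMSE and mean SD
against issue date shows how skill and confidence evolve as the season
approaches — both should shrink toward the event.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .forecast import ForecastProduct

__all__ = ["lookup_forecast", "verify", "error_distribution"]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["latitude", "longitude", "species", "phenophase", "observed_doy"]
VERIFICATION_COLUMNS = ["issue_day", "n_events", "rmse", "mean_sd", "mean_error"]


def lookup_forecast(
    product: ForecastProduct, latitude: float, longitude: float
) -> tuple[float, float] | None:
    """Point estimate and SD at the grid cell nearest a coordinate.

    Ties in distance resolve to the lower cell index.  Returns ``None``
    when the nearest cell is missing (outside the species range or not
    forecastable); raises for coordinates outside the grid bounds.
    """
    lats = product.data["lat"].values
    lons = product.data["lon"].values
    half_lat = np.median(np.abs(np.diff(lats))) / 2 if len(lats) > 1 else 1.0
    half_lon = np.median(np.abs(np.diff(lons))) / 2 if len(lons) > 1 else 1.0
    if not (lats.min() - half_lat <= latitude <= lats.max() + half_lat):
        raise ValueError(f"latitude {latitude} outside grid bounds")
    if not (lons.min() - half_lon <= longitude <= lons.max() + half_lon):
        raise ValueError(f"longitude {longitude} outside grid bounds")
    i = int(np.argmin(np.abs(lats - latitude)))
    j = int(np.argmin(np.abs(lons - longitude)))
    point = float(product.data["prediction"].values[i, j])
    sd = float(product.data["sd"].values[i, j])
    if np.isnan(point):
        return None
    return point, sd


def _match_events(products: list[ForecastProduct], events: pd.DataFrame) -> pd.DataFrame:
    """Pair each event with its species/phenophase forecast values."""
    rows = []
    dropped = 0
    by_key = {(p.species, p.phenophase): p for p in products}
    for _, ev in events.iterrows():
        prod = by_key.get((ev["species"], ev["phenophase"]))
        if prod is None:
            dropped += 1
            continue
        hit = lookup_forecast(prod, ev["latitude"], ev["longitude"])
        if hit is None:
            dropped += 1
            continue
        rows.append(
            {
                "issue_day": prod.issue_day,
                "observed_doy": float(ev["observed_doy"]),
                "predicted": hit[0],
                "sd": hit[1],
            }
        )
    if dropped:
        logger.info("dropped %d events with no matching forecast cell", dropped)
    return pd.DataFrame(rows, columns=["issue_day", "observed_doy", "predicted", "sd"])


def verify(
    products_by_issue: dict[int, list[ForecastProduct]],
    events: pd.DataFrame,
    mode: str = "forecastable",
) -> pd.DataFrame:
    """Score each issue date's forecasts against observed events.

    Per issue date, over the matched events: ``rmse`` is
    ``sqrt(mean((predicted - observed)^2))``, ``mean_sd`` the mean
    forecast SD, and ``mean_error`` the mean signed error (positive =
    over-prediction, i.e. predicted later than observed).

    ``mode`` selects which events each issue date is scored on:
    ``"forecastable"`` (default) scores only events that had not yet
    occurred on the issue date — genuine forecasts; ``"all"`` scores
    every matched event regardless of timing.
    """
    if mode not in ("forecastable", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for issue_day in sorted(products_by_issue):
        matched = _match_events(products_by_issue[issue_day], events)
        if mode == "forecastable" and not matched.empty:
            matched = matched[matched["observed_doy"] >= issue_day]
        if matched.empty:
            rows.append({"issue_day": issue_day, "n_events": 0, "rmse": np.nan,
                         "mean_sd": np.nan, "mean_error": np.nan})
            continue
        err = matched["predicted"] - matched["observed_doy"]
        rows.append(
            {
                "issue_day": issue_day,
                "n_events": len(matched),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mean_sd": float(matched["sd"].mean()),
                "mean_error": float(err.mean()),
            }
        )
    return pd.DataFrame(rows, columns=VERIFICATION_COLUMNS)


def error_distribution(
    products_by_issue: dict[int, list[ForecastProduct]],
    events: pd.DataFrame,
    issue_days: list[int] | None = None,
    mode: str = "forecastable",
) -> dict[int, dict]:
    """Signed forecast errors and their mean absolute value per issue date.

    Returns ``{issue_day: {"errors": array, "mae": float}}`` for the
    selected subset of issue dates (all by default).  Errors are
    ``predicted - observed`` in days.
    """
    if issue_days is None:
        issue_days = sorted(products_by_issue)
    out: dict[int, dict] = {}
    for issue_day in issue_days:
        matched = _match_events(products_by_issue[issue_day], events)
        if mode == "forecastable" and not matched.empty:
            matched = matched[matched["observed_doy"] >= issue_day]
        errors = (matched["predicted"] - matched["observed_doy"]).to_numpy()
        out[issue_day] = {
            "errors": errors,
            "mae": float(np.mean(np.abs(errors))) if len(errors) else np.nan,
        }
    return out
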