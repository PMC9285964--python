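"""Seeded synthetic inputs with known ground truth.

Every input the forecasting pipeline consumes — daily fine-grid
temperatures, coarse 6-h forecast cubes, raw status records, onset
tables, climate-member ensembles, species range masks — can be
generated here from a :class:`SyntheticTruth`, so the whole system is
testable offline and end-to-end identifiable: with all noise terms at
zero the pipeline must reproduce the truth exactly.

The temperature climate is a sinusoidal annual cycle with a latitudinal
lapse::

    T(d) = mean - lapse * (lat - lat0) + amplitude * sin(2*pi*(d - phase)/365) + eps

which captures the features the models care about (a cold winter, a
warming spring, colder conditions northward) while remaining fully
parametric.  Each generator draws from its own random stream keyed by
``(seed, purpose-tag)`` so adding a generator never perturbs existing
fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .downscaling import idw_weights, month_of_day
from .models import (
    NO_EVENT,
    DailyTemperatureSeries,
    ModelParameters,
    make_cube,
    predict_matrix,
)

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "rng_for",
    "synth_temperature_cube",
    "synth_sites",
    "site_series_from_cube",
    "synth_observations",
    "inject_filter_violations",
    "synth_coarse_fine_pair",
    "daily_to_six_hourly",
    "synth_climate_members",
    "synth_range_mask",
]


def rng_for(seed: int, purpose: str) -> np.random.Generator:
    """Independent random stream for one generator purpose.

    Streams are keyed by ``(seed, crc32(purpose))`` so each generator's
    draws are stable regardless of call order or other generators.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(purpose.encode())]))


@dataclass
class SyntheticTruth:
    """Ground truth behind all synthetic fixtures.

    Climate parameters are deg C; ``lapse`` is deg C per degree
    latitude northward of ``lat0``; ``phase`` places the annual minimum
    in mid-January.  ``obs_noise_sd`` is the SD (days) of the
    observation error added to true onset dates.
    """

    seed: int = 0
    reference_year: int = 2018
    mean: float = 10.0
    amplitude: float = 12.0
    lapse: float = 0.8
    lat0: float = 35.0
    phase: float = 105.0
    noise_sd: float = 2.0
    obs_noise_sd: float = 2.0
    species_models: dict = field(default_factory=dict)
    lat_range: tuple = (35.0, 45.0)
    lon_range: tuple = (-100.0, -90.0)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """Truth with two spring species driven by different model families."""
    truth = SyntheticTruth(seed=seed, **overrides)
    if not truth.species_models:
        truth.species_models = {
            "species_a": ModelParameters(
                "thermal_time", {"t1": 1, "T_base": 5.0, "F_star": 300.0}
            ),
            "species_b": ModelParameters(
                "thermal_time", {"t1": -30, "T_base": 2.0, "F_star": 420.0}
            ),
        }
    return truth


def _climatology(truth: SyntheticTruth, lats: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Noise-free (lat, day) temperature surface."""
    seasonal = truth.amplitude * np.sin(2 * np.pi * (days - truth.phase) / 365.0)
    lat_term = -truth.lapse * (lats - truth.lat0)
    return lat_term[:, None] + truth.mean + seasonal[None, :]


def synth_temperature_cube(
    truth: SyntheticTruth,
    nlat: int = 10,
    nlon: int = 10,
    start_day: int = -60,
    n_days: int = 330,
    purpose: str = "fine-temps",
) -> xr.DataArray:
    """Daily fine-grid temperature cube from the synthetic climate."""
    lats = np.linspace(truth.lat_range[0], truth.lat_range[1], nlat)
    lons = np.linspace(truth.lon_range[0], truth.lon_range[1], nlon)
    days = np.arange(start_day, start_day + n_days)
    clim = _climatology(truth, lats, days)  # (nlat, ndays)
    vals = np.broadcast_to(clim[:, None, :], (nlat, nlon, n_days)).copy()
    if truth.noise_sd > 0:
        rng = rng_for(truth.seed, purpose)
        vals += rng.normal(0.0, truth.noise_sd, size=vals.shape)
    return make_cube(vals, lats, lons, start_day, reference_year=truth.reference_year)


def synth_sites(truth: SyntheticTruth, cube: xr.DataArray, n: int,
                purpose: str = "sites") -> pd.DataFrame:
    """Sample ``n`` observation sites at random grid cells (with reuse)."""
    rng = rng_for(truth.seed, purpose)
    nlat, nlon = cube.sizes["lat"], cube.sizes["lon"]
    ii = rng.integers(0, nlat, size=n)
    jj = rng.integers(0, nlon, size=n)
    return pd.DataFrame(
        {
            "site_id": [f"site_{i:04d}" for i in range(n)],
            "lat_index": ii,
            "lon_index": jj,
            "latitude": cube["lat"].values[ii],
            "longitude": cube["lon"].values[jj],
        }
    )


def site_series_from_cube(
    cube: xr.DataArray, sites: pd.DataFrame, year: int
) -> dict:
    """Per-site daily temperature series keyed by ``(site_id, year)``."""
    cube = cube.transpose("lat", "lon", "time")
    start = int(cube["time"].values[0])
    out = {}
    for _, s in sites.iterrows():
        vals = cube.values[int(s["lat_index"]), int(s["lon_index"]), :]
        out[(s["site_id"], year)] = DailyTemperatureSeries(start, vals.copy())
    return out


def _day_to_date(day, reference_year: int) -> np.ndarray:
    origin = np.datetime64(f"{reference_year - 1}-12-31")
    return origin + np.asarray(day, dtype=int).astype("timedelta64[D]")


def synth_observations(
    truth: SyntheticTruth,
    cube: xr.DataArray,
    species: str,
    phenophase: str = "budburst",
    n: int = 100,
    purpose: str = "observations",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate onset observations and matching raw status records.

    Onsets are the true model's prediction at each site plus rounded
    Normal(0, ``obs_noise_sd``) error.  Status records are constructed
    to pass the 30-day prior-no filter (a "no" 7 days before each
    "yes", then a confirming "yes" 7 days after).  Sites where the true
    model predicts no event are skipped.

    Returns ``(status_records, observations, sites)``.
    """
    params = truth.species_models[species]
    rng = rng_for(truth.seed, f"{purpose}:{species}:{phenophase}")
    sites = synth_sites(truth, cube, n, purpose=f"{purpose}-sites:{species}:{phenophase}")
    cube_t = cube.transpose("lat", "lon", "time")
    start = int(cube_t["time"].values[0])
    T = cube_t.values[sites["lat_index"].to_numpy(), sites["lon_index"].to_numpy(), :]
    true_day, status = predict_matrix(T, start, params)

    year = truth.reference_year
    obs_rows, status_rows = [], []
    n_skipped = 0
    for i, s in sites.iterrows():
        if true_day[i] == NO_EVENT:
            n_skipped += 1
            continue
        onset = int(true_day[i])
        if truth.obs_noise_sd > 0:
            onset += int(np.rint(rng.normal(0.0, truth.obs_noise_sd)))
        plant = f"plant_{i:04d}"
        base = {
            "plant_id": plant, "site_id": s["site_id"],
            "latitude": s["latitude"], "longitude": s["longitude"],
            "species": species, "phenophase": phenophase,
        }
        for offset, st in ((-7, "no"), (0, "yes"), (7, "yes")):
            status_rows.append(
                {**base, "date": str(_day_to_date(onset + offset, year)), "status": st}
            )
        obs_rows.append({**base, "year": year, "onset_doy": onset})
    if n_skipped:
        import logging
        logging.getLogger(__name__).info(
            "%d of %d sites skipped (true model predicts no event)", n_skipped, n
        )
    observations = pd.DataFrame(obs_rows)
    status_records = pd.DataFrame(status_rows)
    return status_records, observations, sites


def inject_filter_violations(status_records: pd.DataFrame,
                             reference_year: int = 2018) -> pd.DataFrame:
    """Append records that the status filter must reject.

    Adds one plant with conflicting same-day yes/no records and one
    plant with two yes-series inside 12 months; neither may yield an
    onset.
    """
    proto = status_records.iloc[0].to_dict() if len(status_records) else {
        "site_id": "site_x", "latitude": 40.0, "longitude": -95.0,
        "species": "species_a", "phenophase": "budburst",
    }
    extra = []
    base = {k: proto[k] for k in ("site_id", "latitude", "longitude", "species", "phenophase")}
    d = lambda day: str(_day_to_date(day, reference_year))  # noqa: E731
    # conflicting same-day statuses
    extra += [
        {**base, "plant_id": "plant_conflict", "date": d(90), "status": "no"},
        {**base, "plant_id": "plant_conflict", "date": d(100), "status": "yes"},
        {**base, "plant_id": "plant_conflict", "date": d(100), "status": "no"},
    ]
    # two yes-series within a 12-month period
    extra += [
        {**base, "plant_id": "plant_double", "date": d(80), "status": "no"},
        {**base, "plant_id": "plant_double", "date": d(95), "status": "yes"},
        {**base, "plant_id": "plant_double", "date": d(120), "status": "no"},
        {**base, "plant_id": "plant_double", "date": d(140), "status": "yes"},
    ]
    return pd.concat([status_records, pd.DataFrame(extra)], ignore_index=True)


def synth_coarse_fine_pair(
    truth: SyntheticTruth,
    n_years: int = 2,
    fine_dims: tuple = (3, 3),
    coarse_dims: tuple = (4, 4),
    affine_noise_sd: float = 0.0,
    start_day: int = 1,
    n_days: int | None = None,
    purpose: str = "archive",
) -> tuple[xr.DataArray, xr.DataArray, xr.Dataset]:
    """Paired coarse and fine daily archives with known affine maps.

    The coarse archive follows the synthetic climate on a coarser grid
    that encloses the fine grid.  The fine archive is the IDW regrid of
    the coarse one with a per-cell, per-calendar-month affine map
    applied (plus optional Normal noise), so the asynchronous-regression
    fit has an exact recoverable truth.  The affine maps depend only on
    ``(seed, "truth-maps", fine_dims)``, so a season generated with a
    different ``purpose`` shares the maps of the training archive.

    Returns ``(coarse_archive, fine_archive, true_maps)`` where
    ``true_maps`` is a Dataset with ``slope``/``intercept`` on
    (lat, lon, month).
    """
    rng = rng_for(truth.seed, purpose)
    if n_days is None:
        n_days = 365 * n_years
    pad = 0.5  # coarse grid extends past the fine grid so IDW interpolates
    clat = np.linspace(truth.lat_range[0] - pad, truth.lat_range[1] + pad, coarse_dims[0])
    clon = np.linspace(truth.lon_range[0] - pad, truth.lon_range[1] + pad, coarse_dims[1])
    days = np.arange(start_day, start_day + n_days)
    clim = _climatology(truth, clat, days)
    cvals = np.broadcast_to(clim[:, None, :], (len(clat), len(clon), n_days)).copy()
    if truth.noise_sd > 0:
        cvals += rng.normal(0.0, truth.noise_sd, size=cvals.shape)
    coarse = make_cube(cvals, clat, clon, start_day, reference_year=truth.reference_year)

    flat_ = np.linspace(truth.lat_range[0], truth.lat_range[1], fine_dims[0])
    flon = np.linspace(truth.lon_range[0], truth.lon_range[1], fine_dims[1])
    map_rng = rng_for(truth.seed, f"truth-maps:{fine_dims[0]}x{fine_dims[1]}")
    slopes = map_rng.uniform(0.7, 1.3, size=(fine_dims[0], fine_dims[1], 12))
    intercepts = map_rng.uniform(-3.0, 3.0, size=(fine_dims[0], fine_dims[1], 12))

    fl, fn = np.meshgrid(flat_, flon, indexing="ij")
    pts = np.column_stack([fl.ravel(), fn.ravel()])
    idx, w = idw_weights(clat, clon, pts)
    flatc = cvals.reshape(-1, n_days)
    coarse_at_fine = np.einsum("nk,nkt->nt", w, flatc[idx]).reshape(
        fine_dims[0], fine_dims[1], n_days
    )
    months = month_of_day(days, truth.reference_year) - 1
    a = slopes[:, :, months]
    b = intercepts[:, :, months]
    fvals = a * coarse_at_fine + b
    if affine_noise_sd > 0:
        fvals = fvals + rng.normal(0.0, affine_noise_sd, size=fvals.shape)
    fine = make_cube(fvals, flat_, flon, start_day, reference_year=truth.reference_year)
    true_maps = xr.Dataset(
        {
            "slope": (("lat", "lon", "month"), slopes),
            "intercept": (("lat", "lon", "month"), intercepts),
        },
        coords={"lat": flat_, "lon": flon, "month": np.arange(1, 13)},
    )
    return coarse, fine, true_maps


def daily_to_six_hourly(cube: xr.DataArray, diurnal_amplitude: float = 5.0) -> xr.DataArray:
    """Expand a daily cube to 6-h steps with a diurnal harmonic.

    Each day's four values are the daily mean plus ``diurnal_amplitude *
    (0, 1, 0, -1)`` (coldest at 18:00 UTC-style offset is not modelled;
    only the zero-mean diurnal cycle matters here), so aggregating back
    to daily means recovers the input exactly.
    """
    cube = cube.transpose("lat", "lon", "time")
    days = np.asarray(cube["time"].values, dtype=int)
    harmonic = diurnal_amplitude * np.array([0.0, 1.0, 0.0, -1.0])
    vals = cube.values[:, :, :, None] + harmonic[None, None, None, :]
    vals = vals.reshape(cube.shape[0], cube.shape[1], -1)
    t6 = (days[:, None] + np.array([0.0, 0.25, 0.5, 0.75])[None, :]).ravel()
    out = xr.DataArray(
        vals, dims=("lat", "lon", "time"),
        coords={"lat": cube["lat"], "lon": cube["lon"], "time": t6},
        name="tmean", attrs=dict(cube.attrs),
    )
    return out


def synth_climate_members(
    base: xr.DataArray,
    n_members: int = 5,
    spread_per_30d: float = 0.5,
    seed: int = 0,
    knot_spacing: int = 15,
    purpose: str = "members",
) -> list[xr.DataArray]:
    """Perturbed copies of a base cube emulating a forecast ensemble.

    Member 0 is the base itself; each other member adds a smooth random
    perturbation whose SD grows linearly with lead time at
    ``spread_per_30d`` deg C per 30 days from the cube start.  Spread 0
    gives identical members.
    """
    if n_members < 1:
        raise ValueError("need at least one member")
    rng = rng_for(seed, purpose)
    base = base.transpose("lat", "lon", "time")
    days = np.asarray(base["time"].values, dtype=int)
    lead = (days - days[0]).astype(float)
    scale = spread_per_30d * lead / 30.0
    members = [base.copy()]
    n_knots = max(2, int(np.ceil(len(days) / knot_spacing)) + 1)
    knots = np.linspace(0, len(days) - 1, n_knots)
    for _ in range(1, n_members):
        knot_vals = rng.normal(0.0, 1.0, size=n_knots)
        smooth = np.interp(np.arange(len(days)), knots, knot_vals)
        pert = smooth * scale  # shared across cells: large-scale forecast error
        member = base.copy(data=base.values + pert[None, None, :])
        members.append(member)
    return members


def synth_range_mask(cube: xr.DataArray, truth: SyntheticTruth,
                     fraction: float = 1.0, purpose: str = "range-mask") -> np.ndarray:
    """Boolean species range covering a random ``fraction`` of cells."""
    nlat, nlon = cube.sizes["lat"], cube.sizes["lon"]
    if fraction >= 1.0:
        return np.ones((nlat, nlon), dtype=bool)
    rng = rng_for(truth.seed, purpose)
    return rng.random((nlat, nlon)) < fraction
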