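"""Single-shot pipeline commands: fit, build-downscaling, forecast, verify.

Each command is a plain function taking a :class:`RunConfig`; the
command-line interface in :mod:`phenocast.cli` is a thin wrapper.  The
forecast command writes all products to a staging directory and only
renames it into the publish directory when every product succeeded, so
an interrupted or failing run never leaves a partial publication and
consumers always see the latest complete forecast set.

Scheduling (the operational system re-runs every few days from cron) is
deliberately out of scope: these are idempotent one-shot runners.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .downscaling import apply_downscaling, build_downscaling_model
from .evaluation import verify
from .fitting import (
    FitError,
    default_family_specs,
    filter_status_records,
    fit_latitude_baseline,
    fit_stacked_ensemble,
    predict_ensemble_grid,
    require_min_observations,
)
from .forecast import apply_range_mask, assemble_member, compute_anomaly, summarize_members
from .models import DailyTemperatureSeries
from .synthetic import default_truth  # noqa: F401  (re-exported for the synth command)

__all__ = ["RunConfig", "PipelineError", "cmd_fit", "cmd_build_downscaling",
           "cmd_forecast", "cmd_verify", "cmd_synth"]

logger = logging.getLogger("phenocast.pipeline")

#: Default minimum forecast horizon: a member must reach 9 months
#: (270 days) past the issue date or it is discarded for a fallback.
DEFAULT_MIN_HORIZON_DAYS = 270

OBSERVED_START = {"1nov": -60, "30nov": -31}


class PipelineError(RuntimeError):
    """A pipeline command could not produce its contracted output."""


@dataclass
class RunConfig:
    """Explicit configuration for one pipeline run.

    ``issue_day`` and ``observed_start`` are extended day indices
    (day 1 = 1 January of ``reference_year``); ``observed_start`` may
    also be the policy strings ``"1nov"`` (-60) or ``"30nov"`` (-31).
    """

    status_records: str | None = None
    onset_table: str | None = None
    temperature_archive: str | None = None
    coarse_archive: str | None = None
    fine_archive: str | None = None
    observed_cube: str | None = None
    members: list = field(default_factory=list)
    fallback_members: list = field(default_factory=list)
    downscaling_model: str | None = None
    model_store: str = "models"
    publish_dir: str = "publish"
    range_masks: dict = field(default_factory=dict)
    events: str | None = None
    issue_day: int = 1
    reference_year: int = 2018
    n_members: int = 5
    observed_start: int | str = "1nov"
    min_horizon_days: int = DEFAULT_MIN_HORIZON_DAYS
    n_min_observations: int = 30
    k_folds: int = 100
    seed: int = 0
    fit_maxiter: int = 120
    fit_popsize: int = 20
    model_version: str = "0.1.0"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.observed_start, str):
            key = self.observed_start.lower().replace(" ", "")
            if key not in OBSERVED_START:
                raise ValueError(f"observed_start must be '1nov', '30nov' or an integer day")
            self.observed_start = OBSERVED_START[key]
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _log_step(step: str, t0: float, outcome: str, **fields) -> None:
    extra = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("step=%s duration=%.2fs outcome=%s %s", step, time.time() - t0, outcome, extra)


def _site_temps(obs: pd.DataFrame, cube, reference_year: int) -> dict:
    """Nearest-cell daily series for each observation's site and year."""
    cube = cube.transpose("lat", "lon", "time")
    lats, lons = cube["lat"].values, cube["lon"].values
    start = int(cube["time"].values[0])
    temps = {}
    for (site, year), grp in obs.groupby(["site_id", "year"]):
        row = grp.iloc[0]
        i = int(np.argmin(np.abs(lats - row["latitude"])))
        j = int(np.argmin(np.abs(lons - row["longitude"])))
        temps[(site, year)] = DailyTemperatureSeries(start, cube.values[i, j, :].copy())
    return temps


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def cmd_fit(config: RunConfig) -> Path:
    """Fit ensembles and baselines for every qualifying group.

    Reads onset observations (or derives them from raw status records),
    drops groups below the observation threshold, fits the stacked
    ensemble plus latitude baseline per species x phenophase, and
    writes one JSON model document per group plus a metadata index.
    Groups that fail to fit are logged and skipped; the command raises
    only if every group fails.
    """
    t0 = time.time()
    if config.onset_table:
        obs, rejects = pio.read_observations(config.onset_table)
        if len(rejects):
            logger.warning("rejected %d malformed observation rows", len(rejects))
    elif config.status_records:
        obs = filter_status_records(pio.read_status_records(config.status_records))
    else:
        raise PipelineError("cmd_fit needs onset_table or status_records")
    if config.temperature_archive is None:
        raise PipelineError("cmd_fit needs a temperature_archive")
    cube = pio.read_grid(config.temperature_archive)

    obs = require_min_observations(obs, config.n_min_observations)
    groups = list(obs.groupby(["species", "phenophase"]))
    if not groups:
        raise PipelineError(
            f"no species x phenophase group has >= {config.n_min_observations} observations"
        )
    store = Path(config.model_store)
    store.mkdir(parents=True, exist_ok=True)
    index = {"schema_version": pio.SCHEMA_VERSION, "seed": config.seed, "models": []}
    n_failed = 0
    for (species, phase), grp in groups:
        tg = time.time()
        try:
            temps = _site_temps(grp, cube, config.reference_year)
            ensemble = fit_stacked_ensemble(
                grp, temps, default_family_specs(), k=config.k_folds,
                seed=config.seed, maxiter=config.fit_maxiter, popsize=config.fit_popsize,
            )
            baseline = fit_latitude_baseline(grp)
        except FitError as exc:
            n_failed += 1
            _log_step("fit", tg, "skipped", species=species, phenophase=phase, reason=exc)
            continue
        doc = pio.ensemble_to_document(ensemble, species, phase, baseline)
        fname = f"{species}__{phase}.json"
        pio.save_model(doc, store / fname)
        index["models"].append(
            {"species": species, "phenophase": phase, "file": fname,
             "n_obs": int(len(grp)), "stacked_oof_rmse": ensemble.metadata["stacked_oof_rmse"]}
        )
        _log_step("fit", tg, "ok", species=species, phenophase=phase, n_obs=len(grp))
    if groups and n_failed == len(groups):
        raise PipelineError("every species x phenophase group failed to fit")
    (store / "metadata.json").write_text(json.dumps(index, indent=2, sort_keys=True) + "\n")
    _log_step("cmd_fit", t0, "ok", n_models=len(index["models"]), n_skipped=n_failed)
    return store


# ---------------------------------------------------------------------------
# build-downscaling
# ---------------------------------------------------------------------------

def cmd_build_downscaling(config: RunConfig) -> Path:
    """Fit the per-cell/month downscaling model from paired archives."""
    t0 = time.time()
    if not (config.coarse_archive and config.fine_archive):
        raise PipelineError("cmd_build_downscaling needs coarse_archive and fine_archive")
    coarse = pio.read_grid(config.coarse_archive)
    fine = pio.read_grid(config.fine_archive)
    model = build_downscaling_model(coarse, fine, config.reference_year)
    out = Path(config.downscaling_model or "downscaling_model.nc")
    pio.write_downscaling_model(model, out)
    _log_step("cmd_build_downscaling", t0, "ok", cells=model.slope.shape[:2])
    return out


# ---------------------------------------------------------------------------
# forecast
# ---------------------------------------------------------------------------

def _member_horizon_ok(member_cube, issue_day: int, min_horizon: int) -> bool:
    end = float(np.asarray(member_cube["time"].values).max())
    return end >= issue_day + min_horizon


def _load_members(config: RunConfig) -> list:
    """Load member forecast cubes, replacing short ones from fallbacks."""
    members, fallbacks = list(config.members), list(config.fallback_members)
    loaded = []
    for path in members:
        cube = pio.read_grid(path)
        while not _member_horizon_ok(cube, config.issue_day, config.min_horizon_days):
            if not fallbacks:
                logger.warning("member %s too short and no fallback left; discarded", path)
                cube = None
                break
            fb = fallbacks.pop(0)
            logger.info("member %s too short; falling back to %s", path, fb)
            path = fb
            cube = pio.read_grid(fb)
        if cube is not None:
            loaded.append(cube)
    return loaded


def cmd_forecast(config: RunConfig) -> Path:
    """Run the full gridded forecast and publish atomically.

    For each stored model: splice observed temperatures with every
    downscaled member, predict, summarize across members, compute the
    anomaly, crop to the species range, and write one product file.
    All files go to a staging directory that replaces the issue date's
    publish directory only if every product succeeded.
    """
    t0 = time.time()
    store = Path(config.model_store)
    index_path = store / "metadata.json"
    if not index_path.exists():
        raise PipelineError(f"model store index not found at {index_path}")
    index = json.loads(index_path.read_text())
    if config.observed_cube is None or config.downscaling_model is None:
        raise PipelineError("cmd_forecast needs observed_cube and downscaling_model")
    observed = pio.read_grid(config.observed_cube)
    observed = observed.isel(
        time=np.asarray(observed["time"].values, dtype=int) >= int(config.observed_start)
    )
    ds_model = pio.read_downscaling_model(config.downscaling_model)
    member_cubes = _load_members(config)
    if not member_cubes:
        raise PipelineError("no valid climate members after fallback")

    climate_members = []
    for mid, raw in enumerate(member_cubes):
        downscaled = apply_downscaling(raw, ds_model, config.reference_year)
        climate_members.append(assemble_member(observed, downscaled, config.issue_day, mid))
    span = (
        int(climate_members[0].cube["time"].values[0]),
        int(climate_members[0].cube["time"].values[-1]),
    )

    publish_root = Path(config.publish_dir)
    publish_root.mkdir(parents=True, exist_ok=True)
    target = publish_root / f"issue_{config.issue_day:+04d}"
    staging = publish_root / f".staging_issue_{config.issue_day:+04d}"
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir()
    try:
        for entry in index["models"]:
            tg = time.time()
            species, phase = entry["species"], entry["phenophase"]
            doc = pio.load_model(store / entry["file"])
            ensemble, baseline = pio.document_to_ensemble(doc)
            grids = [predict_ensemble_grid(m.cube, ensemble) for m in climate_members]
            summary = summarize_members(grids, day_span=span)
            if baseline is None:
                raise PipelineError(f"model {species}/{phase} has no latitude baseline")
            anomaly = compute_anomaly(summary["point_estimate"], baseline)
            mask_path = config.range_masks.get(species)
            if mask_path:
                mask = pio.read_grid(mask_path).values.astype(bool)
            else:
                mask = np.ones(summary["point_estimate"].shape, dtype=bool)
            product = apply_range_mask(summary, anomaly, mask, species, phase, config.issue_day)
            pio.write_product(
                product, staging / f"{species}__{phase}.nc", model_version=config.model_version
            )
            _log_step("forecast", tg, "ok", species=species, phenophase=phase)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        logger.error("forecast run failed; publish directory left untouched")
        raise
    if target.exists():
        shutil.rmtree(target)
    staging.rename(target)
    _log_step("cmd_forecast", t0, "ok", n_products=len(index["models"]),
              n_members=len(climate_members))
    return target


# ---------------------------------------------------------------------------
# verify
# ---------------------------------------------------------------------------

def cmd_verify(config: RunConfig, events_path: str | Path | None = None) -> pd.DataFrame:
    """Score every published issue date against observed events."""
    t0 = time.time()
    events_path = events_path or config.events
    if events_path is None:
        raise PipelineError("cmd_verify needs an events CSV")
    events = pd.read_csv(events_path)
    publish_root = Path(config.publish_dir)
    issue_dirs = sorted(publish_root.glob("issue_*"))
    if not issue_dirs:
        raise PipelineError(f"no published products under {publish_root}")
    products_by_issue = {}
    for d in issue_dirs:
        products = [pio.read_product(p) for p in sorted(d.glob("*.nc"))]
        if products:
            products_by_issue[products[0].issue_day] = products
    table = verify(products_by_issue, events)
    out = publish_root / "verification.csv"
    pio.write_table(table, out)
    _log_step("cmd_verify", t0, "ok", n_issue_dates=len(table))
    return table


# ---------------------------------------------------------------------------
# synth
# ---------------------------------------------------------------------------

def cmd_synth(out_dir: str | Path, seed: int = 0, nlat: int = 10, nlon: int = 10,
              n_obs: int = 40, n_members: int = 5, issue_days: tuple = (-30, 30, 90),
              spread_per_30d: float = 0.5, obs_noise_sd: float = 2.0,
              noise_sd: float = 2.0, season_start: int = -60,
              season_days: int = 330) -> Path:
    """Generate a complete synthetic input set for the pipeline.

    One seeded truth drives everything: a two-year coarse/fine training
    archive for the downscaling model, a season of "observed" fine-grid
    weather (itself the downscaled image of a season-long coarse run, so
    the pipeline is exactly identifiable at zero noise), per-issue-date
    6-h member forecast cubes with lead-time-growing spread, raw status
    records, an onset table, events for verification, and a ready-made
    YAML config per issue date.
    """
    import yaml

    from .synthetic import (
        daily_to_six_hourly,
        synth_climate_members,
        synth_coarse_fine_pair,
        synth_observations,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = default_truth(seed, obs_noise_sd=obs_noise_sd, noise_sd=noise_sd)

    # training archive (two years) and the forecast season share affine maps
    coarse_arch, fine_arch, _ = synth_coarse_fine_pair(
        truth, n_years=2, fine_dims=(nlat, nlon), purpose="archive")
    pio.write_grid(coarse_arch, out / "coarse_archive.nc")
    pio.write_grid(fine_arch, out / "fine_archive.nc")
    coarse_season, fine_season, _ = synth_coarse_fine_pair(
        truth, fine_dims=(nlat, nlon), start_day=season_start,
        n_days=season_days, purpose="season")
    pio.write_grid(fine_season, out / "observed_temperature.nc")

    status_frames, obs_frames = [], []
    for species in truth.species_models:
        status, obs_df, _ = synth_observations(truth, fine_season, species, n=n_obs)
        status_frames.append(status)
        obs_frames.append(obs_df)
    pio.write_table(pd.concat(status_frames, ignore_index=True), out / "status_records.csv")
    obs_all = pd.concat(obs_frames, ignore_index=True)
    pio.write_table(obs_all, out / "observations.csv")
    events = obs_all.rename(columns={"onset_doy": "observed_doy"})[
        ["latitude", "longitude", "species", "phenophase", "observed_doy"]
    ]
    pio.write_table(events, out / "events.csv")

    season_end = season_start + season_days - 1
    for issue in issue_days:
        t = np.asarray(coarse_season["time"].values, dtype=int)
        base = coarse_season.isel(time=t >= int(issue))
        members = synth_climate_members(base, n_members=n_members,
                                        spread_per_30d=spread_per_30d,
                                        seed=seed + issue + 1000)
        mdir = out / "members" / f"issue_{issue:+04d}"
        mdir.mkdir(parents=True, exist_ok=True)
        member_paths = []
        for i, m in enumerate(members):
            path = mdir / f"member_{i}.nc"
            pio.write_grid(daily_to_six_hourly(m), path)
            member_paths.append(str(path))
        config = {
            "status_records": str(out / "status_records.csv"),
            "onset_table": str(out / "observations.csv"),
            "temperature_archive": str(out / "observed_temperature.nc"),
            "coarse_archive": str(out / "coarse_archive.nc"),
            "fine_archive": str(out / "fine_archive.nc"),
            "observed_cube": str(out / "observed_temperature.nc"),
            "members": member_paths,
            "downscaling_model": str(out / "downscaling_model.nc"),
            "model_store": str(out / "models"),
            "publish_dir": str(out / "publish"),
            "events": str(out / "events.csv"),
            "issue_day": int(issue),
            "reference_year": truth.reference_year,
            "n_members": n_members,
            "min_horizon_days": int(season_end - max(issue_days)) - 1,
            "seed": seed,
        }
        (out / f"config_issue_{issue:+04d}.yaml").write_text(yaml.safe_dump(config))
    logger.info("synthetic inputs written to %s", out)
    return out
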