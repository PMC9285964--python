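"""Observation filtering, model fitting, and stacked ensembles.

Raw phenology monitoring data is status based: volunteers repeatedly
answer "yes", "no", or "unsure" to whether a phenophase is present on a
marked plant.  :func:`filter_status_records` turns those records into
onset events using the conservative rule that a "yes" only counts when
the same plant had a "no" within the prior 30 days, and drops plants
with conflicting or ambiguous records.

For each species x phenophase group with enough observations, four
process models (see :mod:`phenocast.models`) are fit by seeded bounded
global optimization and combined by *stacking*: out-of-fold predictions
from k-fold cross-validation are used to learn non-negative weights
summing to one that minimize held-out RMSE, after which each member is
refit on the full data.  A latitude-only linear baseline is fit
alongside for computing forecast anomalies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .models import (
    FAMILIES,
    FAMILY_PARAMS,
    NO_EVENT,
    STATUS_EVENT,
    DailyTemperatureSeries,
    ModelParameters,
    predict_matrix,
)

__all__ = [
    "FamilySpec",
    "StackedEnsemble",
    "LatitudeBaseline",
    "filter_status_records",
    "require_min_observations",
    "fit_single_model",
    "fit_stacked_ensemble",
    "stacking_weights",
    "predict_ensemble",
    "predict_ensemble_grid",
    "fit_latitude_baseline",
    "default_family_specs",
]

#: Cost (in days) charged for an observation the model predicts no event
#: for; large enough to dominate any real misfit but finite so the
#: optimizer can climb out of dead regions.
NO_EVENT_PENALTY_DAY = 1000.0

STATUS_COLUMNS = [
    "plant_id", "site_id", "latitude", "longitude",
    "species", "phenophase", "date", "status",
]
OBSERVATION_COLUMNS = [
    "plant_id", "site_id", "latitude", "longitude",
    "species", "phenophase", "year", "onset_doy",
]


class FitError(RuntimeError):
    """Raised when a model cannot be fit to an observation group."""


# ---------------------------------------------------------------------------
# Observation filtering
# ---------------------------------------------------------------------------

def filter_status_records(records: pd.DataFrame) -> pd.DataFrame:
    """Derive onset events from raw yes/no/unsure status records.

    A plant's onset for a phenophase is the first "yes" of a yes-series
    that has a "no" record for the same plant and phenophase within the
    preceding 30 days.  Plants with conflicting same-day statuses, or
    with more than one yes-series for a phenophase within a 12-month
    period, are dropped entirely for that phenophase.  "unsure" records
    are ignored.

    Parameters
    ----------
    records
        DataFrame with columns ``plant_id, site_id, latitude, longitude,
        species, phenophase, date, status``; ``date`` parseable to a
        datestamp, ``status`` in {"yes", "no", "unsure"}.

    Returns
    -------
    DataFrame with one row per onset: ``plant_id, site_id, latitude,
    longitude, species, phenophase, year, onset_doy`` where ``onset_doy``
    is the day of year of the onset.
    """
    df = records.copy()
    missing_cols = [c for c in STATUS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"status records missing columns {missing_cols}")
    bad_status = ~df["status"].isin(["yes", "no", "unsure"])
    if bad_status.any():
        raise ValueError(f"invalid status values at rows {list(df.index[bad_status])}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="mixed")
    except (ValueError, TypeError):
        bad_rows = []
        for i, v in df["date"].items():
            try:
                pd.to_datetime(v)
            except (ValueError, TypeError):
                bad_rows.append(i)
        raise ValueError(f"unparseable dates at rows {bad_rows}")

    df = df[df["status"] != "unsure"]
    onsets: list[dict] = []
    for (plant, phase), grp in df.groupby(["plant_id", "phenophase"], sort=True):
        grp = grp.sort_values("date", kind="stable")
        # conflicting records: same date, both yes and no
        per_day = grp.groupby("date")["status"].nunique()
        if (per_day > 1).any():
            continue
        grp = grp.drop_duplicates(subset="date")
        status = grp["status"].to_numpy()
        dates = grp["date"].to_numpy()
        is_yes = status == "yes"
        # series starts: a yes not immediately preceded (in record order) by a yes
        starts = is_yes & ~np.roll(is_yes, 1)
        if is_yes[:1].size:
            starts[0] = is_yes[0]
        start_dates = dates[starts]
        # more than one yes-series within any 12-month period -> drop plant/phase
        if len(start_dates) > 1:
            gaps = np.diff(start_dates).astype("timedelta64[D]").astype(int)
            if (gaps < 365).any():
                continue
        no_dates = dates[~is_yes]
        first_row = grp.iloc[0]
        for sd in start_dates:
            prior = (no_dates < sd) & (no_dates >= sd - np.timedelta64(30, "D"))
            if not prior.any():
                continue
            ts = pd.Timestamp(sd)
            onsets.append(
                {
                    "plant_id": plant,
                    "site_id": first_row["site_id"],
                    "latitude": float(first_row["latitude"]),
                    "longitude": float(first_row["longitude"]),
                    "species": first_row["species"],
                    "phenophase": phase,
                    "year": int(ts.year),
                    "onset_doy": int(ts.dayofyear),
                }
            )
    return pd.DataFrame(onsets, columns=OBSERVATION_COLUMNS)


def require_min_observations(table: pd.DataFrame, n_min: int = 30) -> pd.DataFrame:
    """Keep only species x phenophase groups with at least ``n_min`` rows."""
    if table.empty:
        return table.copy()
    counts = table.groupby(["species", "phenophase"])["onset_doy"].transform("size")
    return table[counts >= n_min].copy()


# ---------------------------------------------------------------------------
# Single-model fitting
# ---------------------------------------------------------------------------

#: Default optimizer bounds per family; chosen to cover temperate
#: spring phenology on the extended day axis.
DEFAULT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "thermal_time": {"t1": (-60, 120), "T_base": (-5, 15), "F_star": (10, 1000)},
    "alternating": {"t1": (-60, 60), "a": (0, 1500), "b": (0, 1500), "c": (-2, 0)},
    # b_sig < 0 so forcing increases with temperature
    "uniforc": {"t1": (-60, 120), "b_sig": (-5, -0.05), "c_sig": (0, 25), "F_star": (5, 300)},
    "linear": {},
}


@dataclass
class FamilySpec:
    """How to fit one model family: free-parameter bounds and fixed values.

    ``fixed`` entries are held constant during optimization; all other
    parameters of the family are searched within ``bounds`` (defaulting
    to :data:`DEFAULT_BOUNDS`).  A spec with every parameter fixed is a
    prescribed (not fitted) member.
    """

    family: str
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        merged = dict(DEFAULT_BOUNDS[self.family])
        merged.update(self.bounds)
        self.bounds = merged

    def free_params(self) -> list[str]:
        names = [p for p in FAMILY_PARAMS[self.family] if p not in self.fixed]
        if self.family == "alternating" and "chill_threshold" in names:
            names.remove("chill_threshold")  # fixed at the 5 degC literature default
        if self.family == "linear":
            return []  # closed-form OLS, no search
        return names


def default_family_specs() -> list[FamilySpec]:
    """The standard four-member ensemble specification."""
    return [
        FamilySpec("thermal_time"),
        FamilySpec("alternating"),
        FamilySpec("uniforc"),
        FamilySpec("linear", fixed={"window_start": 1, "window_end": 60}),
    ]


def _stack_series(
    obs: pd.DataFrame, temps: dict
) -> tuple[np.ndarray, int, np.ndarray]:
    """Row-stack each observation's temperature series on a common axis.

    ``temps`` maps ``(site_id, year)`` to a DailyTemperatureSeries; all
    series are trimmed to their common span.  Returns ``(T, start_day,
    observed)`` where ``observed`` are the onset days.
    """
    keys = list(zip(obs["site_id"], obs["year"]))
    missing = [k for k in keys if k not in temps]
    if missing:
        raise FitError(f"no temperature series for {sorted(set(missing))[:5]} ...")
    series = [temps[k] for k in keys]
    start = max(s.start_day for s in series)
    end = min(s.end_day for s in series)
    if end < start:
        raise FitError("temperature series have no common span")
    n_days = end - start + 1
    T = np.empty((len(series), n_days))
    for i, s in enumerate(series):
        off = start - s.start_day
        T[i] = s.values[off : off + n_days]
    return T, start, obs["onset_doy"].to_numpy(dtype=float)


def _predicted_days(T: np.ndarray, start_day: int, params: ModelParameters) -> np.ndarray:
    day, status = predict_matrix(T, start_day, params)
    out = day.astype(float)
    out[status != STATUS_EVENT] = NO_EVENT_PENALTY_DAY
    return out


def _rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _fit_linear(T, start_day, observed, spec: FamilySpec) -> ModelParameters:
    w0 = int(spec.fixed.get("window_start", 1))
    w1 = int(spec.fixed.get("window_end", 60))
    days = np.arange(start_day, start_day + T.shape[1])
    sel = (days >= w0) & (days <= w1)
    if not sel.any():
        raise FitError("linear window outside temperature span")
    x = T[:, sel].mean(axis=1)
    if np.ptp(x) < 1e-12:
        beta1, beta0 = 0.0, float(np.mean(observed))
    else:
        beta1, beta0 = np.polyfit(x, observed, 1)
    return ModelParameters(
        "linear",
        {"beta0": float(beta0), "beta1": float(beta1), "window_start": w0, "window_end": w1},
    )


def fit_single_model(
    obs: pd.DataFrame,
    temps: dict,
    spec: FamilySpec | str,
    seed: int = 0,
    maxiter: int = 120,
    popsize: int = 20,
) -> ModelParameters:
    """Fit one phenology model to an observation group by minimizing RMSE.

    Uses seeded differential evolution over the spec's free parameters
    (no polishing; the objective is stepwise in the integer event day).
    Observations the candidate model predicts no event for are charged a
    large finite penalty so such regions are strongly disfavoured.

    Parameters
    ----------
    obs
        Observation rows for a single species x phenophase group.
    temps
        Mapping ``(site_id, year) -> DailyTemperatureSeries`` covering
        each observation's accumulation window.
    spec
        FamilySpec (or family name for all-default fitting).
    seed
        Seed for the global optimizer; fixed seed => reproducible fit.
    """
    if isinstance(spec, str):
        spec = FamilySpec(spec)
    if len(obs) < 2:
        raise FitError(f"need at least 2 observations, got {len(obs)}")
    T, start_day, observed = _stack_series(obs, temps)

    if spec.family == "linear":
        return _fit_linear(T, start_day, observed, spec)

    free = spec.free_params()
    if not free:  # fully prescribed member
        return ModelParameters(spec.family, dict(spec.fixed))
    bounds = []
    for name in free:
        if name not in spec.bounds:
            raise ValueError(f"no bounds for free parameter {name!r}")
        lo, hi = spec.bounds[name]
        if not np.isfinite([lo, hi]).all():
            raise ValueError(f"unbounded search space for {name!r}")
        bounds.append((lo, hi))

    def objective(x: np.ndarray) -> float:
        p = dict(spec.fixed)
        p.update(zip(free, x))
        try:
            params = ModelParameters(spec.family, p)
        except ValueError:
            return NO_EVENT_PENALTY_DAY * 10
        return _rmse(_predicted_days(T, start_day, params), observed)

    result = differential_evolution(
        objective,
        bounds,
        seed=seed,
        tol=1e-4,
        maxiter=maxiter,
        popsize=popsize,
        polish=False,
    )
    p = dict(spec.fixed)
    p.update(zip(free, result.x))
    return ModelParameters(spec.family, p)


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

@dataclass
class StackedEnsemble:
    """Weighted ensemble of fitted phenology models.

    ``weights`` lie on the simplex (non-negative, summing to one) and
    were learned by stacking on out-of-fold predictions; ``members``
    are the final full-data refits.
    """

    members: list
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if (self.weights < -1e-12).any() or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = np.clip(self.weights, 0.0, None)
        self.weights = self.weights / self.weights.sum()


def stacking_weights(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares stacking weights constrained to the simplex.

    Minimizes ``||P w - y||`` subject to ``w >= 0`` and ``sum(w) = 1``.
    Exact ties (all member columns identical) resolve to the uniform
    point; otherwise the optimizer is started from both the uniform
    point and the best single member's vertex and the better solution
    is kept, so the stacked in-sample RMSE never exceeds the best
    member's.
    """
    n, m = P.shape
    if np.allclose(P, P[:, :1], atol=1e-12):
        return np.full(m, 1.0 / m)
    member_rmse = np.sqrt(np.mean((P - y[:, None]) ** 2, axis=0))
    best_vertex = np.eye(m)[int(np.argmin(member_rmse))]

    def obj(w):
        r = P @ w - y
        return float(r @ r) / n

    cons = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    bnds = [(0.0, 1.0)] * m
    candidates = []
    for x0 in (np.full(m, 1.0 / m), best_vertex):
        res = minimize(obj, x0, method="SLSQP", bounds=bnds, constraints=cons,
                       options={"maxiter": 500, "ftol": 1e-12})
        w = np.clip(res.x, 0.0, None)
        w = w / w.sum()
        candidates.append(w)
    candidates.append(best_vertex)
    objs = [obj(w) for w in candidates]
    best = int(np.argmin(objs))
    # prefer the uniform-start solution on exact ties
    if objs[0] <= objs[best] + 1e-12:
        best = 0
    return candidates[best]


def fit_stacked_ensemble(
    obs: pd.DataFrame,
    temps: dict,
    specs: list | None = None,
    k: int = 100,
    seed: int = 0,
    maxiter: int = 120,
    popsize: int = 20,
) -> StackedEnsemble:
    """Fit the weighted model ensemble for one species x phenophase group.

    Procedure: (1) randomly partition the observations into ``k`` folds
    (reduced to leave-one-out when the group is smaller than ``k``);
    (2) fit every member family on each training fold and predict its
    held-out fold, assembling one out-of-fold prediction per observation
    per family; (3) choose weights on the simplex minimizing the RMSE of
    the weighted out-of-fold prediction; (4) refit every family on the
    full data set.  The returned ensemble carries the full-data members
    with the cross-validated weights.
    """
    if specs is None:
        specs = default_family_specs()
    n = len(obs)
    if n < 2:
        raise FitError("need at least 2 observations for stacking")
    if k > n:
        warnings.warn(f"k={k} folds > {n} observations; using leave-one-out", stacklevel=2)
        k = n
    rng = np.random.default_rng(seed)
    fold_of = np.arange(n) % k  # every fold non-empty for k <= n
    rng.shuffle(fold_of)

    obs = obs.reset_index(drop=True)
    P = np.empty((n, len(specs)))
    for j, spec in enumerate(specs):
        for f in range(k):
            test = fold_of == f
            train_obs = obs[~test]
            fitted = fit_single_model(
                train_obs, temps, spec, seed=seed + 7919 * f + j,
                maxiter=maxiter, popsize=popsize,
            )
            T, start_day, _ = _stack_series(obs[test], temps)
            P[test, j] = _predicted_days(T, start_day, fitted)

    y = obs["onset_doy"].to_numpy(dtype=float)
    weights = stacking_weights(P, y)
    member_oof_rmse = [_rmse(P[:, j], y) for j in range(len(specs))]
    stacked_oof_rmse = _rmse(P @ weights, y)

    members = [
        fit_single_model(obs, temps, spec, seed=seed + j, maxiter=maxiter, popsize=popsize)
        for j, spec in enumerate(specs)
    ]
    return StackedEnsemble(
        members,
        weights,
        metadata={
            "n_obs": n,
            "k_folds": k,
            "seed": seed,
            "member_oof_rmse": member_oof_rmse,
            "stacked_oof_rmse": stacked_oof_rmse,
        },
    )


# ---------------------------------------------------------------------------
# Ensemble prediction
# ---------------------------------------------------------------------------

#: Minimum total weight of members that must predict an event for the
#: ensemble to return a date; below this the forecast is withheld.
MIN_RESPONDING_WEIGHT = 0.5


def predict_ensemble(series: DailyTemperatureSeries, ensemble: StackedEnsemble) -> int:
    """Weighted-mean event day of the ensemble members for one site.

    Members predicting no event are excluded and the remaining weights
    renormalized; if less than half the total weight responds, the
    ensemble returns :data:`~phenocast.models.NO_EVENT`.
    """
    from .models import predict_event_day

    days = np.array([predict_event_day(series, m) for m in ensemble.members], dtype=float)
    responding = days != NO_EVENT
    w = ensemble.weights[responding]
    if w.sum() < MIN_RESPONDING_WEIGHT:
        return NO_EVENT
    return int(np.rint(np.sum(days[responding] * w) / w.sum()))


def predict_ensemble_grid(cube, ensemble: StackedEnsemble):
    """Weighted-mean event day of the ensemble over a temperature cube.

    Returns a Dataset like :func:`phenocast.models.predict_grid` —
    variables ``day`` and ``status`` on dims ``(lat, lon)`` — applying
    the same responder-weight rule per cell as :func:`predict_ensemble`.
    """
    import xarray as xr

    from .models import STATUS_MISSING, STATUS_NO_EVENT, predict_grid

    member_out = [predict_grid(cube, m) for m in ensemble.members]
    day_stack = np.stack([mo["day"].values for mo in member_out])  # (m, lat, lon)
    status_stack = np.stack([mo["status"].values for mo in member_out])
    responding = status_stack == STATUS_EVENT
    w = ensemble.weights[:, None, None] * responding
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore"):
        day = np.rint(np.nansum(day_stack * w, axis=0) / wsum)
    ok = wsum >= MIN_RESPONDING_WEIGHT
    all_missing = (status_stack == STATUS_MISSING).all(axis=0)
    status = np.where(ok, STATUS_EVENT, STATUS_NO_EVENT).astype(np.int8)
    status[all_missing] = STATUS_MISSING
    day = np.where(ok, day, np.nan)
    return xr.Dataset(
        {"day": (("lat", "lon"), day), "status": (("lat", "lon"), status)},
        coords={"lat": member_out[0]["lat"], "lon": member_out[0]["lon"]},
    )


# ---------------------------------------------------------------------------
# Latitude baseline
# ---------------------------------------------------------------------------

@dataclass
class LatitudeBaseline:
    """Long-term average event day as a linear function of latitude.

    ``expected_day = beta0 + beta1 * latitude``; used to express a
    forecast as an anomaly against the spatially corrected average.
    """

    beta0: float
    beta1: float

    def expected_day(self, latitude):
        return self.beta0 + self.beta1 * np.asarray(latitude, dtype=float)


def fit_latitude_baseline(obs: pd.DataFrame) -> LatitudeBaseline:
    """Ordinary least squares of onset day on latitude."""
    lat = obs["latitude"].to_numpy(dtype=float)
    y = obs["onset_doy"].to_numpy(dtype=float)
    if np.unique(lat).size < 2:
        raise FitError("latitude baseline needs at least 2 distinct latitudes")
    beta1, beta0 = np.polyfit(lat, y, 1)
    return LatitudeBaseline(float(beta0), float(beta1))
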