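"""Readers and writers for every artifact the pipeline produces.

This module is the single format authority for the package:

* fitted ensembles and latitude baselines — text-based JSON documents
  with a ``schema_version``, stable key ordering and full float
  precision, so model stores diff cleanly under version control;
* temperature cubes, forecast products and downscaling models — netCDF
  with named dimensions (lat, lon, time / month), CF-style attributes
  and an integer extended-day time coordinate (``days since 31 Dec`` of
  the year before the reference year, so day 1 = 1 January);
* observation, status and verification tables — CSV with documented
  headers.

Grids are stored row-major north-to-south only by convention of the
caller; the coordinate variables are authoritative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .downscaling import DownscalingModel
from .fitting import (
    OBSERVATION_COLUMNS,
    STATUS_COLUMNS,
    LatitudeBaseline,
    StackedEnsemble,
)
from .forecast import ForecastProduct
from .models import FAMILIES, ModelParameters

__all__ = [
    "SCHEMA_VERSION",
    "ensemble_to_document",
    "document_to_ensemble",
    "save_model",
    "load_model",
    "write_grid",
    "read_grid",
    "write_product",
    "read_product",
    "write_downscaling_model",
    "read_downscaling_model",
    "read_observations",
    "read_status_records",
    "write_table",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


def _nc_engine() -> str:
    try:
        import netCDF4  # noqa: F401
        return "netcdf4"
    except ImportError:
        return "scipy"


def _compression(engine: str) -> dict:
    return {"zlib": True, "complevel": 4} if engine == "netcdf4" else {}


# ---------------------------------------------------------------------------
# JSON model store
# ---------------------------------------------------------------------------

def ensemble_to_document(
    ensemble: StackedEnsemble,
    species: str,
    phenophase: str,
    baseline: LatitudeBaseline | None = None,
) -> dict:
    """Build the JSON-serializable model document for one ensemble."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "species": species,
        "phenophase": phenophase,
        "members": [
            {"family": m.family, "params": {k: float(v) for k, v in m.params.items()}}
            for m in ensemble.members
        ],
        "weights": [float(w) for w in ensemble.weights],
        "fit_metadata": {
            k: (v if not isinstance(v, (np.floating, np.integer)) else v.item())
            for k, v in ensemble.metadata.items()
        },
    }
    if baseline is not None:
        doc["baseline"] = {"beta0": float(baseline.beta0), "beta1": float(baseline.beta1)}
    return doc


def _validate_document(doc: dict) -> None:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {doc.get('schema_version')!r}; "
            f"this build reads version {SCHEMA_VERSION}"
        )
    members = doc.get("members")
    if not members:
        raise SchemaError("document has no members")
    for m in members:
        if m.get("family") not in FAMILIES:
            raise SchemaError(f"unknown model family {m.get('family')!r}")
        for k, v in m.get("params", {}).items():
            if v is None or not np.isfinite(v):
                raise SchemaError(f"non-finite parameter {k}={v!r}")
    weights = np.asarray(doc.get("weights", []), dtype=float)
    if len(weights) != len(members):
        raise SchemaError("one weight per member required")
    if (weights < -1e-9).any() or abs(weights.sum() - 1.0) > 1e-6:
        raise SchemaError("weights must be non-negative and sum to 1")


def document_to_ensemble(doc: dict) -> tuple[StackedEnsemble, LatitudeBaseline | None]:
    """Reconstruct the ensemble (and baseline, if stored) from a document."""
    _validate_document(doc)
    members = [ModelParameters(m["family"], m["params"]) for m in doc["members"]]
    ensemble = StackedEnsemble(members, np.asarray(doc["weights"], dtype=float),
                               metadata=dict(doc.get("fit_metadata", {})))
    baseline = None
    if "baseline" in doc:
        baseline = LatitudeBaseline(doc["baseline"]["beta0"], doc["baseline"]["beta1"])
    return ensemble, baseline


def save_model(doc: dict, path: str | Path) -> Path:
    """Write a model document as deterministic, diff-friendly JSON."""
    _validate_document(doc)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def load_model(path: str | Path) -> dict:
    """Load and validate a model document."""
    doc = json.loads(Path(path).read_text())
    _validate_document(doc)
    return doc


# ---------------------------------------------------------------------------
# netCDF grids
# ---------------------------------------------------------------------------

def _time_attrs(reference_year: int | None) -> dict:
    attrs = {"long_name": "extended day index (day 1 = 1 January of the reference year)"}
    if reference_year is not None:
        attrs["units"] = f"days since {int(reference_year) - 1}-12-31"
    return attrs


def write_grid(cube: xr.DataArray, path: str | Path) -> Path:
    """Write a temperature cube (variable ``tmean``) as netCDF."""
    path = Path(path)
    engine = _nc_engine()
    ds = cube.to_dataset(name="tmean")
    ds["lat"].attrs.setdefault("units", "degrees_north")
    ds["lon"].attrs.setdefault("units", "degrees_east")
    if "time" in ds.dims:
        ds["time"].attrs.update(_time_attrs(cube.attrs.get("reference_year")))
    enc = {"tmean": {"dtype": "float32", **_compression(engine)}}
    ds.to_netcdf(path, engine=engine, encoding=enc)
    return path


def read_grid(path: str | Path) -> xr.DataArray:
    """Read a temperature cube written by :func:`write_grid`."""
    path = Path(path)
    try:
        ds = xr.open_dataset(path, engine=_nc_engine(), decode_times=False)
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read netCDF grid {path}: {exc}") from exc
    with ds:
        if "tmean" not in ds:
            raise SchemaError(f"{path} is missing required variable 'tmean'")
        cube = ds["tmean"].load()
    cube.attrs.update(ds.attrs)
    return cube


def write_product(product: ForecastProduct, path: str | Path,
                  model_version: str = "unversioned") -> Path:
    """Write a forecast product as one compressed netCDF file.

    Dimensions (lat, lon); variables ``prediction, sd, pi_low, pi_high,
    anomaly`` plus the boolean ``range_mask``; identity carried as
    global attributes.
    """
    path = Path(path)
    engine = _nc_engine()
    ds = product.data.copy()
    ds["range_mask"] = (("lat", "lon"), product.range_mask.astype(np.int8))
    ds.attrs.update(
        {
            "species": product.species,
            "phenophase": product.phenophase,
            "issue_day": int(product.issue_day),
            "model_version": model_version,
        }
    )
    comp = _compression(engine)
    enc = {v: {"dtype": "float32", **comp} for v in
           ("prediction", "sd", "pi_low", "pi_high", "anomaly")}
    enc["range_mask"] = {"dtype": "int8", **comp}
    ds.to_netcdf(path, engine=engine, encoding=enc)
    return path


def read_product(path: str | Path) -> ForecastProduct:
    """Read a forecast product written by :func:`write_product`."""
    path = Path(path)
    try:
        ds = xr.open_dataset(path, engine=_nc_engine(), decode_times=False)
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read forecast product {path}: {exc}") from exc
    with ds:
        required = ["prediction", "sd", "pi_low", "pi_high", "anomaly", "range_mask"]
        missing = [v for v in required if v not in ds]
        if missing:
            raise SchemaError(f"{path} is missing required variables {missing}")
        data = ds[["prediction", "sd", "pi_low", "pi_high", "anomaly"]].load()
        mask = ds["range_mask"].values.astype(bool)
        attrs = dict(ds.attrs)
    return ForecastProduct(
        species=str(attrs.get("species", "")),
        phenophase=str(attrs.get("phenophase", "")),
        issue_day=int(attrs.get("issue_day", 0)),
        data=data,
        range_mask=mask,
        attrs=attrs,
    )


def write_downscaling_model(model: DownscalingModel, path: str | Path) -> Path:
    """Store the per-cell/month affine maps as netCDF (lat, lon, month)."""
    path = Path(path)
    engine = _nc_engine()
    ds = xr.Dataset(
        {
            "slope": (("lat", "lon", "month"), model.slope),
            "intercept": (("lat", "lon", "month"), model.intercept),
        },
        coords={"lat": model.lats, "lon": model.lons, "month": np.arange(1, 13)},
        attrs={k: v for k, v in model.attrs.items()},
    )
    comp = _compression(engine)
    enc = {v: {"dtype": "float64", **comp} for v in ("slope", "intercept")}
    ds.to_netcdf(path, engine=engine, encoding=enc)
    return path


def read_downscaling_model(path: str | Path) -> DownscalingModel:
    """Read a downscaling model written by :func:`write_downscaling_model`."""
    try:
        ds = xr.open_dataset(path, engine=_nc_engine(), decode_times=False)
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read downscaling model {path}: {exc}") from exc
    with ds:
        for v in ("slope", "intercept"):
            if v not in ds:
                raise SchemaError(f"{path} is missing required variable {v!r}")
        model = DownscalingModel(
            ds["lat"].values, ds["lon"].values,
            ds["slope"].values, ds["intercept"].values,
            attrs=dict(ds.attrs),
        )
    return model


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_observations(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an onset-observation CSV.

    Returns ``(table, rejects)``: typed valid rows, and the unparseable
    rows with a ``reason`` column.  Raises when the header is missing
    required columns.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"observation CSV missing columns {missing}")
    numeric = {"latitude": float, "longitude": float, "year": int, "onset_doy": int}
    good_rows, rejects = [], []
    for i, row in df.iterrows():
        parsed = dict(row)
        try:
            for col, typ in numeric.items():
                parsed[col] = typ(float(row[col]))
        except (ValueError, TypeError):
            rejects.append({**row, "reason": "unparseable numeric field", "row": i})
            continue
        good_rows.append(parsed)
    table = pd.DataFrame(good_rows, columns=OBSERVATION_COLUMNS)
    return table, pd.DataFrame(rejects)


def read_status_records(path: str | Path) -> pd.DataFrame:
    """Read a raw yes/no/unsure status-record CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in STATUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"status CSV missing columns {missing}")
    for col in ("latitude", "longitude"):
        df[col] = df[col].astype(float)
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any tabular artifact (observations, verification) as CSV."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path
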