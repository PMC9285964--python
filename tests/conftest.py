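import numpy as np
import pandas as pd
import pytest

from phenocast.models import DailyTemperatureSeries, ModelParameters
from phenocast.synthetic import (
    default_truth,
    site_series_from_cube,
    synth_observations,
    synth_temperature_cube,
)


@pytest.fixture(scope="session")
def warm_series():
    """Constant 10 degC over days 1..200."""
    return DailyTemperatureSeries(1, np.full(200, 10.0))


@pytest.fixture(scope="session")
def tt_params():
    return ModelParameters("thermal_time", {"t1": 1, "T_base": 0.0, "F_star": 100.0})


@pytest.fixture(scope="session")
def noisy_fit_case():
    """100 sites, thermal_time truth (F*=300, T_base=5, t1=1), onset noise 2 d."""
    truth = default_truth(101, obs_noise_sd=2.0, noise_sd=2.0)
    cube = synth_temperature_cube(truth, nlat=8, nlon=8)
    _, obs, sites = synth_observations(truth, cube, "species_a", n=100)
    temps = site_series_from_cube(cube, sites, truth.reference_year)
    return truth, obs, temps


@pytest.fixture()
def toy_status_records():
    """12 status records: one clean series, one conflicting-status plant,
    one double-yes-series plant.  Exactly one onset must survive."""
    rows = []
    base = {
        "site_id": "s1", "latitude": 40.0, "longitude": -95.0,
        "species": "acer", "phenophase": "budburst",
    }
    # clean: no day 80, yes day 95, yes day 102 -> onset at day 95
    rows += [
        {**base, "plant_id": "clean", "date": "2018-03-21", "status": "no"},
        {**base, "plant_id": "clean", "date": "2018-04-05", "status": "yes"},
        {**base, "plant_id": "clean", "date": "2018-04-12", "status": "yes"},
    ]
    # conflicting same-day yes and no
    rows += [
        {**base, "plant_id": "conflict", "date": "2018-03-21", "status": "no"},
        {**base, "plant_id": "conflict", "date": "2018-04-05", "status": "yes"},
        {**base, "plant_id": "conflict", "date": "2018-04-05", "status": "no"},
        {**base, "plant_id": "conflict", "date": "2018-04-12", "status": "yes"},
    ]
    # two yes-series inside 12 months
    rows += [
        {**base, "plant_id": "double", "date": "2018-03-11", "status": "no"},
        {**base, "plant_id": "double", "date": "2018-03-26", "status": "yes"},
        {**base, "plant_id": "double", "date": "2018-04-30", "status": "no"},
        {**base, "plant_id": "double", "date": "2018-05-20", "status": "yes"},
        {**base, "plant_id": "double", "date": "2018-05-27", "status": "yes"},
    ]
    return pd.DataFrame(rows)
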