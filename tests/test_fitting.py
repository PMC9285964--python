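"""Tests for observation filtering, model fitting, and stacking."""

import numpy as np
import pandas as pd
import pytest

from phenocast.fitting import (
    FamilySpec,
    FitError,
    LatitudeBaseline,
    StackedEnsemble,
    _predicted_days,
    _stack_series,
    filter_status_records,
    fit_latitude_baseline,
    fit_single_model,
    fit_stacked_ensemble,
    predict_ensemble,
    require_min_observations,
    stacking_weights,
)
from phenocast.models import NO_EVENT, DailyTemperatureSeries, ModelParameters


class TestFilterStatusRecords:
    def test_yes_with_recent_prior_no_yields_onset(self):
        df = pd.DataFrame(
            [
                {"plant_id": "p", "site_id": "s", "latitude": 40.0, "longitude": -95.0,
                 "species": "x", "phenophase": "budburst", "date": "2018-03-21",
                 "status": "no"},
                {"plant_id": "p", "site_id": "s", "latitude": 40.0, "longitude": -95.0,
                 "species": "x", "phenophase": "budburst", "date": "2018-04-05",
                 "status": "yes"},
            ]
        )
        out = filter_status_records(df)
        assert len(out) == 1
        assert out.iloc[0]["onset_doy"] == 95

    def test_yes_without_prior_no_yields_nothing(self):
        df = pd.DataFrame(
            [
                {"plant_id": "p", "site_id": "s", "latitude": 40.0, "longitude": -95.0,
                 "species": "x", "phenophase": "budburst", "date": "2018-04-05",
                 "status": "yes"},
            ]
        )
        assert len(filter_status_records(df)) == 0

    def test_no_too_far_back_does_not_qualify(self):
        df = pd.DataFrame(
            [
                {"plant_id": "p", "site_id": "s", "latitude": 40.0, "longitude": -95.0,
                 "species": "x", "phenophase": "budburst", "date": "2018-02-01",
                 "status": "no"},
                {"plant_id": "p", "site_id": "s", "latitude": 40.0, "longitude": -95.0,
                 "species": "x", "phenophase": "budburst", "date": "2018-04-05",
                 "status": "yes"},
            ]
        )
        assert len(filter_status_records(df)) == 0

    def test_toy_set_keeps_exactly_one_onset(self, toy_status_records):
        out = filter_status_records(toy_status_records)
        assert len(out) == 1
        assert out.iloc[0]["plant_id"] == "clean"
        assert out.iloc[0]["onset_doy"] == 95

    def test_unsure_records_are_ignored(self, toy_status_records):
        extra = toy_status_records.iloc[[1]].assign(status="unsure", date="2018-04-01")
        out = filter_status_records(pd.concat([toy_status_records, extra]))
        assert len(out) == 1

    def test_idempotent_and_order_insensitive(self, toy_status_records):
        out1 = filter_status_records(toy_status_records)
        shuffled = toy_status_records.sample(frac=1.0, random_state=3)
        out2 = filter_status_records(shuffled)
        pd.testing.assert_frame_equal(
            out1.reset_index(drop=True), out2.reset_index(drop=True)
        )

    def test_malformed_date_raises_with_row_listing(self, toy_status_records):
        bad = toy_status_records.copy()
        bad.loc[2, "date"] = "not-a-date"
        with pytest.raises(ValueError, match="dates"):
            filter_status_records(bad)


class TestRequireMinObservations:
    @pytest.mark.parametrize("n,kept", [(30, True), (29, False)])
    def test_threshold_is_inclusive_at_30(self, n, kept):
        table = pd.DataFrame(
            {
                "species": ["x"] * n, "phenophase": ["budburst"] * n,
                "onset_doy": np.arange(n), "latitude": 40.0, "longitude": -95.0,
                "plant_id": "p", "site_id": "s", "year": 2018,
            }
        )
        out = require_min_observations(table, 30)
        assert (len(out) == n) if kept else out.empty

    def test_empty_table_passes_through(self):
        assert require_min_observations(pd.DataFrame(columns=["species", "phenophase",
                                                              "onset_doy"])).empty


class TestFitSingleModel:
    def test_noiseless_truth_is_recovered_exactly(self):
        """Observations generated from thermal_time refit with zero RMSE."""
        rng = np.random.default_rng(0)
        truth = ModelParameters("thermal_time", {"t1": 1, "T_base": 0.0, "F_star": 200.0})
        temps, rows = {}, []
        for i in range(25):
            base = rng.uniform(6, 12)
            series = DailyTemperatureSeries(1, np.full(250, base))
            from phenocast.models import predict_event_day
            onset = predict_event_day(series, truth)
            temps[(f"s{i}", 2018)] = series
            rows.append({"site_id": f"s{i}", "year": 2018, "onset_doy": onset,
                         "latitude": 40.0, "longitude": -95.0})
        obs = pd.DataFrame(rows)
        spec = FamilySpec("thermal_time", fixed={"t1": 1, "T_base": 0.0})
        fitted = fit_single_model(obs, temps, spec, seed=1)
        T, sd, y = _stack_series(obs, temps)
        assert np.sqrt(np.mean((_predicted_days(T, sd, fitted) - y) ** 2)) == 0.0

    def test_parameter_recovery_under_noise(self, noisy_fit_case):
        """F* recovered within 10% with t1, T_base fixed at truth and 2-d noise."""
        truth, obs, temps = noisy_fit_case
        spec = FamilySpec("thermal_time", fixed={"t1": 1, "T_base": 5.0})
        fitted = fit_single_model(obs.iloc[:70], temps, spec, seed=2)
        assert abs(fitted.params["F_star"] - 300.0) / 300.0 < 0.10

    def test_too_few_observations_raise(self):
        obs = pd.DataFrame([{"site_id": "s", "year": 2018, "onset_doy": 100}])
        with pytest.raises(FitError):
            fit_single_model(obs, {}, FamilySpec("thermal_time"), seed=0)

    def test_unbounded_search_space_rejected(self):
        obs = pd.DataFrame(
            [{"site_id": f"s{i}", "year": 2018, "onset_doy": 100} for i in range(3)]
        )
        temps = {(f"s{i}", 2018): DailyTemperatureSeries(1, np.full(150, 10.0))
                 for i in range(3)}
        spec = FamilySpec("thermal_time", fixed={"t1": 1, "T_base": 0.0},
                          bounds={"F_star": (10, np.inf)})
        with pytest.raises(ValueError, match="[Uu]nbounded"):
            fit_single_model(obs, temps, spec, seed=0)


class TestStackingWeights:
    def test_perfect_member_dominates(self):
        y = np.arange(100, 130, dtype=float)
        P = np.column_stack([y, y + 10, y - 10, y + 25])
        w = stacking_weights(P, y)
        assert w[0] >= 0.99
        assert abs(w.sum() - 1.0) < 1e-6

    def test_symmetric_errors_cancel(self):
        y = np.arange(100, 140, dtype=float)
        P = np.column_stack([y + 8, y - 8, y + 60, y + 80])
        w = stacking_weights(P, y)
        np.testing.assert_allclose(w[:2], [0.5, 0.5], atol=0.01)
        rmse = np.sqrt(np.mean((P @ w - y) ** 2))
        assert rmse < 0.5

    def test_identical_members_resolve_to_uniform(self):
        y = np.arange(100, 120, dtype=float)
        P = np.tile((y + 3)[:, None], (1, 4))
        np.testing.assert_allclose(stacking_weights(P, y), 0.25)

    def test_never_worse_than_best_member(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(80, 150, 60)
        P = y[:, None] + rng.normal(0, 8, (60, 4))
        w = stacking_weights(P, y)
        stacked = np.sqrt(np.mean((P @ w - y) ** 2))
        best = min(np.sqrt(np.mean((P[:, j] - y) ** 2)) for j in range(4))
        assert stacked <= best + 1e-9
        assert (w >= 0).all() and abs(w.sum() - 1) < 1e-6


class TestFitStackedEnsemble:
    def test_true_member_gets_dominant_weight(self, noisy_fit_case):
        """Data from thermal_time; other members prescribed wrong."""
        truth, obs, temps = noisy_fit_case
        specs = [
            FamilySpec("thermal_time", fixed={"t1": 1, "T_base": 5.0}),
            FamilySpec("alternating", fixed={"t1": 1, "a": 800.0, "b": 0.0, "c": -0.01}),
            FamilySpec("uniforc", fixed={"t1": 1, "b_sig": -0.5, "c_sig": 20.0,
                                         "F_star": 40.0}),
            FamilySpec("linear", fixed={"window_start": 1, "window_end": 60,
                                        "beta0": 200.0, "beta1": 0.0}),
        ]
        obs50 = obs.iloc[:50]
        with pytest.warns(UserWarning, match="leave-one-out"):
            ens = fit_stacked_ensemble(obs50, temps, specs, k=100, seed=3)
        assert ens.weights[0] >= 0.8
        assert abs(ens.weights.sum() - 1.0) < 1e-6
        assert ens.metadata["stacked_oof_rmse"] <= min(
            ens.metadata["member_oof_rmse"]) + 1e-9
        # parameter recovery through the stack: held-out error ~ noise level
        assert ens.metadata["stacked_oof_rmse"] <= truth.obs_noise_sd * 1.5

    def test_fold_count_reduces_to_n_with_warning(self, noisy_fit_case):
        _, obs, temps = noisy_fit_case
        spec = [FamilySpec("thermal_time", fixed={"t1": 1, "T_base": 5.0})] * 2
        with pytest.warns(UserWarning):
            ens = fit_stacked_ensemble(obs.iloc[:10], temps, spec, k=100, seed=0)
        assert ens.metadata["k_folds"] == 10

    def test_weights_validation(self):
        m = ModelParameters("thermal_time", {"t1": 1, "T_base": 0.0, "F_star": 100.0})
        with pytest.raises(ValueError):
            StackedEnsemble([m, m], np.array([0.8, 0.4]))
        with pytest.raises(ValueError):
            StackedEnsemble([m, m], np.array([1.5, -0.5]))


class TestPredictEnsemble:
    def _ensemble(self, days, weights):
        members = [
            ModelParameters("thermal_time", {"t1": 1, "T_base": 0.0, "F_star": d * 10.0})
            for d in days
        ]
        return StackedEnsemble(members, np.asarray(weights, float))

    def test_consensus_and_weighted_mean(self, warm_series):
        # constant 10 degC: member with F_star = 10*d predicts day d exactly
        ens = self._ensemble([100, 100, 100, 100], [0.3, 0.3, 0.2, 0.2])
        assert predict_ensemble(warm_series, ens) == 100
        ens = self._ensemble([90, 110, 100, 100], [0.5, 0.5, 0.0, 0.0])
        assert predict_ensemble(warm_series, ens) == 100
        ens = self._ensemble([90, 110, 100, 100], [0.25] * 4)
        assert predict_ensemble(warm_series, ens) == 100

    def test_nonresponding_members_renormalized(self, warm_series):
        # F_star = 1e9 never occurs within 200 days -> non-responder
        members = [
            ModelParameters("thermal_time", {"t1": 1, "T_base": 0.0, "F_star": 1000.0}),
            ModelParameters("thermal_time", {"t1": 1, "T_base": 0.0, "F_star": 1e9}),
        ]
        ens = StackedEnsemble(members, np.array([0.6, 0.4]))
        assert predict_ensemble(warm_series, ens) == 100
        # responding weight below 0.5 -> no forecast
        ens = StackedEnsemble(members, np.array([0.4, 0.6]))
        assert predict_ensemble(warm_series, ens) == NO_EVENT


class TestLatitudeBaseline:
    def _obs(self, lats, days):
        return pd.DataFrame({"latitude": lats, "onset_doy": days})

    def test_exact_gradient_recovered(self):
        lats = np.linspace(35, 45, 11)
        obs = self._obs(lats, 100 + 3.0 * (lats - 35))
        b = fit_latitude_baseline(obs)
        assert b.beta1 == pytest.approx(3.0)
        assert b.expected_day(35.0) == pytest.approx(100.0)

    def test_flat_onsets_give_zero_slope(self):
        obs = self._obs([35, 40, 45], [120, 120, 120])
        b = fit_latitude_baseline(obs)
        assert b.beta1 == pytest.approx(0.0)
        assert b.beta0 == pytest.approx(120.0)

    def test_noisy_recovery_within_two_standard_errors(self):
        rng = np.random.default_rng(8)
        lats = rng.uniform(30, 50, 50)
        y = 200.0 - 2.0 * lats + rng.normal(0, 3, 50)
        b = fit_latitude_baseline(self._obs(lats, y))
        # standard error of the OLS slope
        x = lats - lats.mean()
        resid = y - b.expected_day(lats)
        se = np.sqrt(resid.var(ddof=2) / (x**2).sum())
        assert abs(b.beta1 - (-2.0)) < 2 * se + 1e-9

    def test_single_latitude_is_degenerate(self):
        with pytest.raises(FitError):
            fit_latitude_baseline(self._obs([40.0, 40.0], [100, 110]))
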