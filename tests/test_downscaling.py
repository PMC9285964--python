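"""Tests for IDW regridding and asynchronous-regression downscaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocast.downscaling import (
    DegenerateDataError,
    aggregate_to_daily,
    apply_downscaling,
    build_downscaling_model,
    fit_asynchronous_regression,
    interpolate_idw,
    month_of_day,
)
from phenocast.models import make_cube
from phenocast.synthetic import daily_to_six_hourly, default_truth, synth_coarse_fine_pair


def _six_hourly_cube(vals_daily):
    """vals_daily: (lat, lon, days) -> 6-h cube with the daily value repeated."""
    v = np.repeat(vals_daily, 4, axis=2)
    nlat, nlon = v.shape[:2]
    days = vals_daily.shape[2]
    cube = make_cube(vals_daily, np.arange(nlat), np.arange(nlon), 1)
    return daily_to_six_hourly(cube, diurnal_amplitude=0.0).copy(data=v)


class TestAggregateToDaily:
    def test_mean_of_four_six_hour_values(self):
        vals = np.array([8.0, 10.0, 12.0, 10.0]).reshape(1, 1, 4)
        cube = make_cube(np.zeros((1, 1, 1)), [0], [0], 1)
        six = daily_to_six_hourly(cube).copy(data=vals)
        out = aggregate_to_daily(six)
        assert out.values[0, 0, 0] == pytest.approx(10.0)

    def test_constant_cube_unchanged(self):
        cube = make_cube(np.full((2, 2, 5), 7.0), [0, 1], [0, 1], 1)
        out = aggregate_to_daily(daily_to_six_hourly(cube, diurnal_amplitude=3.0))
        np.testing.assert_allclose(out.values, 7.0)
        np.testing.assert_array_equal(out["time"].values, np.arange(1, 6))

    def test_matches_per_day_loop(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(-5, 25, size=(2, 3, 40))  # 10 days of 6-h steps
        cube = make_cube(np.zeros((2, 3, 10)), [0, 1], [0, 1, 2], 1)
        six = daily_to_six_hourly(cube).copy(data=vals)
        out = aggregate_to_daily(six)
        for d in range(10):
            np.testing.assert_allclose(
                out.values[:, :, d], vals[:, :, 4 * d : 4 * d + 4].mean(axis=2)
            )

    def test_trailing_partial_day_dropped(self):
        cube = make_cube(np.full((1, 1, 3), 5.0), [0], [0], 1)
        six = daily_to_six_hourly(cube).isel(time=slice(0, 10))
        assert aggregate_to_daily(six).sizes["time"] == 2

    def test_non_uniform_steps_rejected(self):
        cube = make_cube(np.full((1, 1, 4), 5.0), [0], [0], 1)
        six = daily_to_six_hourly(cube).isel(time=[0, 1, 3, 4, 5, 6, 7])
        with pytest.raises(ValueError):
            aggregate_to_daily(six)


class TestInterpolateIDW:
    def test_constant_field_everywhere_constant(self):
        coarse = make_cube(np.full((3, 3, 2), 4.5), [0, 1, 2], [0, 1, 2], 1)
        fine = interpolate_idw(coarse, np.linspace(0, 2, 7), np.linspace(0, 2, 7))
        np.testing.assert_allclose(fine.values, 4.5)

    def test_exact_center_match_short_circuits(self):
        vals = np.arange(9.0).reshape(3, 3, 1)
        coarse = make_cube(vals, [0.0, 1.0, 2.0], [0.0, 1.0, 2.0], 1)
        fine = interpolate_idw(coarse, [1.0], [1.0])
        assert fine.values[0, 0, 0] == vals[1, 1, 0]

    def test_midpoint_of_two_centers_averages(self):
        vals = np.array([[0.0], [10.0]]).reshape(2, 1, 1)
        coarse = make_cube(vals, [0.0, 1.0], [0.0], 1)
        fine = interpolate_idw(coarse, [0.5], [0.0], k=2)
        assert fine.values[0, 0, 0] == pytest.approx(5.0)

    def test_point_outside_grid_uses_nearest(self):
        vals = np.array([[0.0], [10.0]]).reshape(2, 1, 1)
        coarse = make_cube(vals, [0.0, 1.0], [0.0], 1)
        fine = interpolate_idw(coarse, [1.8], [0.0])
        assert fine.values[0, 0, 0] == pytest.approx(10.0)


class TestAsynchronousRegression:
    def test_exact_affine_map_survives_any_permutation(self):
        rng = np.random.default_rng(2)
        coarse = rng.uniform(-5, 20, 200)
        fine = 1.5 * coarse - 2.0
        s, i = fit_asynchronous_regression(rng.permutation(coarse), rng.permutation(fine))
        assert s == pytest.approx(1.5, abs=1e-10)
        assert i == pytest.approx(-2.0, abs=1e-9)

    def test_identity_when_fine_is_shuffled_coarse(self):
        rng = np.random.default_rng(3)
        coarse = rng.uniform(0, 15, 90)
        s, i = fit_asynchronous_regression(coarse, rng.permutation(coarse))
        assert s == pytest.approx(1.0, abs=1e-10)
        assert i == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(4)
        coarse = rng.normal(10, 3, 600)
        fine = 0.8 * coarse + 2.0 + rng.normal(0, 0.5, 600)
        s, _ = fit_asynchronous_regression(coarse, fine)
        assert 0.75 <= s <= 0.85

    def test_unequal_lengths_paired_by_quantile(self):
        rng = np.random.default_rng(5)
        coarse = rng.normal(8, 4, 500)
        fine = 1.2 * rng.normal(8, 4, 380) + 1.0
        s, i = fit_asynchronous_regression(coarse, fine)
        assert s == pytest.approx(1.2, abs=0.1)

    def test_too_few_or_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateDataError):
            fit_asynchronous_regression(np.ones(10), np.ones(10))
        with pytest.raises(DegenerateDataError):
            fit_asynchronous_regression(np.ones(50), np.arange(50.0))

    @given(perm_seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance_property(self, perm_seed):
        rng = np.random.default_rng(6)
        coarse = rng.normal(10, 3, 120)
        fine = 0.9 * coarse + 1.0 + rng.normal(0, 0.3, 120)
        ref = fit_asynchronous_regression(coarse, fine)
        p = np.random.default_rng(perm_seed).permutation(120)
        assert fit_asynchronous_regression(coarse[p], fine[p]) == pytest.approx(ref)


class TestBuildAndApply:
    def test_shifted_archive_gives_unit_slope_unit_intercept(self):
        truth = default_truth(10, noise_sd=2.0)
        coarse, _, _ = synth_coarse_fine_pair(truth, n_years=2, fine_dims=(3, 3))
        fine = interpolate_idw(coarse, np.linspace(35, 45, 3), np.linspace(-100, -90, 3))
        fine = fine + 1.0
        model = build_downscaling_model(coarse, fine, truth.reference_year)
        np.testing.assert_allclose(model.slope, 1.0, atol=1e-8)
        np.testing.assert_allclose(model.intercept, 1.0, atol=1e-7)

    def test_known_affine_maps_recovered_exactly(self):
        truth = default_truth(11, noise_sd=0.0)
        coarse, fine, maps = synth_coarse_fine_pair(truth, n_years=2, fine_dims=(3, 3))
        model = build_downscaling_model(coarse, fine, truth.reference_year)
        np.testing.assert_allclose(model.slope, maps["slope"].values, atol=1e-6)
        np.testing.assert_allclose(model.intercept, maps["intercept"].values, atol=1e-6)

    def test_degenerate_month_flagged_not_fabricated(self):
        truth = default_truth(12, noise_sd=0.0, amplitude=0.0, lapse=0.0)
        # constant climate -> zero variance in every month
        coarse, fine, _ = synth_coarse_fine_pair(truth, n_years=2, fine_dims=(2, 2))
        model = build_downscaling_model(coarse, fine, truth.reference_year)
        assert np.isnan(model.slope).all()

    def test_apply_identity_and_affine(self):
        truth = default_truth(13, noise_sd=0.0)
        coarse, fine, maps = synth_coarse_fine_pair(
            truth, fine_dims=(3, 3), start_day=1, n_days=60, purpose="season")
        model = build_downscaling_model(
            *synth_coarse_fine_pair(truth, n_years=2, fine_dims=(3, 3))[:2],
            truth.reference_year)
        out = apply_downscaling(daily_to_six_hourly(coarse), model, truth.reference_year)
        np.testing.assert_allclose(out.values, fine.values, atol=1e-8)

    def test_round_trip_mae_under_noise(self):
        """Model fit on a noisy archive still reconstructs the true fine
        field of an independent season to within 0.2 degC MAE."""
        truth = default_truth(3, noise_sd=2.0)
        coarse_a, fine_a, _ = synth_coarse_fine_pair(
            truth, n_years=2, fine_dims=(3, 3), affine_noise_sd=0.5)
        model = build_downscaling_model(coarse_a, fine_a, truth.reference_year)
        coarse_s, fine_s, _ = synth_coarse_fine_pair(
            truth, fine_dims=(3, 3), start_day=-60, n_days=330, purpose="season")
        out = apply_downscaling(daily_to_six_hourly(coarse_s), model, truth.reference_year)
        assert np.nanmean(np.abs(out.values - fine_s.values)) < 0.2

    def test_monotone_in_coarse_input(self):
        truth = default_truth(14, noise_sd=0.0)
        model = build_downscaling_model(
            *synth_coarse_fine_pair(truth, n_years=2, fine_dims=(2, 2))[:2],
            truth.reference_year)
        coarse, _, _ = synth_coarse_fine_pair(
            truth, fine_dims=(2, 2), start_day=1, n_days=40, purpose="season")
        lo = apply_downscaling(daily_to_six_hourly(coarse), model, truth.reference_year)
        hi = apply_downscaling(daily_to_six_hourly(coarse + 2.0), model,
                               truth.reference_year)
        assert (model.slope > 0).all()
        assert (hi.values >= lo.values).all()


def test_month_of_day_handles_negative_days():
    assert month_of_day(np.array([1]), 2018)[0] == 1
    assert month_of_day(np.array([0]), 2018)[0] == 12
    assert month_of_day(np.array([-60]), 2018)[0] == 11
    assert month_of_day(np.array([365 + 31]), 2018)[0] == 1  # Jan of next year
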