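"""Exponential rise fitting, RMS validation and the tau-vs-R regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from spinaltau import (
    DomainError,
    EstimationError,
    ExponentialRiseEstimator,
    FluidProperties,
    RiseDataset,
    SummaryError,
    TauResistanceRegression,
    equilibration_time_summary,
    fit_exponential_rise,
    rise_height,
    rms_error,
    tau_vs_r_regression,
    times_to_percentages,
)

UNIT_FLUID = FluidProperties(density=1.0, dynamic_viscosity=1.0e-5)


def noiseless_dataset(p=13.0, tau=72.0, n=13, label="synthetic"):
    heights = np.arange(1.0, n + 1.0)
    heights = heights[heights < p]  # stay below the asymptote
    times = -tau * np.log1p(-heights / p)
    return RiseDataset.from_arrays(label, "M1", times, heights)


class TestRiseDatasetValidation:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(DomainError, match="strictly increasing"):
            RiseDataset.from_arrays("n", "M1", [1.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_rejects_decreasing_heights(self):
        with pytest.raises(DomainError, match="nondecreasing"):
            RiseDataset.from_arrays("n", "M1", [1.0, 2.0], [2.0, 1.0])


class TestExponentialFit:
    def test_noiseless_recovery(self):
        data = noiseless_dataset(p=13.0, tau=72.0)
        fit = fit_exponential_rise(data, fluid=UNIT_FLUID)
        assert fit.p_inf == pytest.approx(13.0, rel=1e-6)
        assert fit.tau == pytest.approx(72.0, rel=1e-6)
        assert fit.rmse < 1e-8

    @given(tau=st.floats(10.0, 300.0), p=st.floats(5.0, 40.0))
    @settings(max_examples=40)
    def test_noiseless_recovery_across_parameter_space(self, tau, p):
        data = noiseless_dataset(p=p, tau=tau, n=13)
        fit = fit_exponential_rise(data, fluid=UNIT_FLUID)
        assert fit.p_inf == pytest.approx(p, rel=1e-6)
        assert fit.tau == pytest.approx(tau, rel=1e-6)

    def test_bench_replicates_fit_tightly(self, table2):
        for ds in table2:
            fit = fit_exponential_rise(ds, fluid=UNIT_FLUID)
            assert fit.r_squared >= 0.99, ds.replicate_label

    def test_fitted_curve_reproduces_observations_minus_residuals(self, table2):
        ds = table2[0]
        fit = fit_exponential_rise(ds, fluid=UNIT_FLUID)
        reconstructed = fit.predict(ds.times) + np.asarray(fit.residuals)
        np.testing.assert_allclose(reconstructed, ds.heights, rtol=0, atol=1e-10)

    def test_fixed_tau_mode_is_closed_form_projection(self):
        data = noiseless_dataset(p=13.0, tau=72.0)
        fit = fit_exponential_rise(data, mode="fixed_tau", fluid=UNIT_FLUID, fixed_value=72.0)
        assert fit.p_inf == pytest.approx(13.0, rel=1e-12)
        assert fit.mode == "fixed_tau"

    def test_fixed_p_mode_recovers_tau(self):
        data = noiseless_dataset(p=13.0, tau=111.0)
        fit = fit_exponential_rise(data, mode="fixed_p", fluid=UNIT_FLUID, fixed_value=13.0)
        assert fit.tau == pytest.approx(111.0, rel=1e-6)

    def test_fixed_mode_requires_value(self):
        with pytest.raises(DomainError, match="fixed_value"):
            fit_exponential_rise(noiseless_dataset(), mode="fixed_tau", fluid=UNIT_FLUID)

    def test_degenerate_data_rejected(self):
        flat = RiseDataset.from_arrays("n", "M1", [1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(EstimationError, match="degenerate"):
            fit_exponential_rise(flat, fluid=UNIT_FLUID)

    def test_too_few_observations_rejected(self):
        tiny = RiseDataset.from_arrays("n", "M1", [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DomainError):
            fit_exponential_rise(tiny, fluid=UNIT_FLUID)

    def test_density_scales_pressure_not_height(self):
        data = noiseless_dataset(p=13.0, tau=72.0)
        fit = fit_exponential_rise(data, fluid=FluidProperties(density=1.0006))
        # asymptotic *height* is 13 cm; pressure picks up the rho factor
        assert fit.p_inf == pytest.approx(13.0 * 1.0006, rel=1e-6)


class TestSklearnProtocol:
    def test_get_params_clone_and_predict(self):
        est = ExponentialRiseEstimator(mode="joint", density=1.0)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        data = noiseless_dataset()
        est2.fit(data.times.reshape(-1, 1), data.heights)
        pred = est2.predict(data.times.reshape(-1, 1))
        np.testing.assert_allclose(pred, data.heights, rtol=1e-6)
        assert est2.score(data.times.reshape(-1, 1), data.heights) > 0.999999

    def test_tau_regression_estimator_roundtrip(self, table3):
        R = np.array([r for _, r, _ in table3]).reshape(-1, 1)
        tau = np.array([t for _, _, t in table3])
        est = TauResistanceRegression().fit(R, tau)
        assert est.predict(R).shape == tau.shape
        assert 0.97 < est.r_squared_ <= 1.0


class TestRmsError:
    def test_zero_on_own_curve(self):
        data = noiseless_dataset(p=13.0, tau=72.0)
        assert rms_error(data, 13.0, 72.0) < 1e-10

    def test_constant_offset_gives_offset(self):
        data = noiseless_dataset(p=13.0, tau=72.0)
        shifted = RiseDataset.from_arrays("n", "M1", data.times, data.heights + 0.5)
        assert rms_error(shifted, 13.0, 72.0) == pytest.approx(0.5, rel=1e-9)

    def test_fit_is_locally_optimal_on_parameter_grid(self, table2):
        ds = table2[0]
        fit = fit_exponential_rise(ds, fluid=UNIT_FLUID)
        best = rms_error(ds, fit.p_inf, fit.tau)
        for dp in (-0.5, 0.0, 0.5):
            for dtau in (-5.0, 0.0, 5.0):
                assert best <= rms_error(ds, fit.p_inf + dp, fit.tau + dtau) + 1e-12

    def test_empty_dataset_rejected(self):
        empty = RiseDataset("n", "M1", ())
        with pytest.raises(DomainError, match="empty"):
            rms_error(empty, 13.0, 72.0)


class TestEquilibrationSummary:
    def test_bench_means(self, table2):
        means = equilibration_time_summary(table2, 13.0)
        assert round(means["22G Pajunk Sprotte"]) == 256
        assert means["22G M. Schilling"] == pytest.approx(364.8, abs=0.05)
        assert means["22G Braun Spinocan"] == pytest.approx(470.9, abs=0.05)

    def test_single_replicate_returns_its_own_time(self):
        ds = noiseless_dataset(p=14.0, tau=60.0, n=13)
        means = equilibration_time_summary([ds], 13.0)
        assert means["synthetic"] == ds.times[-1]

    def test_missing_final_height_names_replicate(self):
        ds = noiseless_dataset(p=14.0, tau=60.0, n=10)
        with pytest.raises(SummaryError, match="M1"):
            equilibration_time_summary([ds], 13.0)


class TestTimesToPercentages:
    def test_anchor_values(self):
        fit = fit_exponential_rise(noiseless_dataset(p=13.0, tau=60.0), fluid=UNIT_FLUID)
        t50 = times_to_percentages(fit, [50.0])[0]
        assert t50 == pytest.approx(41.6, abs=0.05)
        fit25 = fit_exponential_rise(noiseless_dataset(p=13.0, tau=25.0), fluid=UNIT_FLUID)
        t958 = times_to_percentages(fit25, [95.8])[0]
        assert t958 == pytest.approx(79.3, abs=0.1)

    def test_monotone_in_percentage(self):
        fit = fit_exponential_rise(noiseless_dataset(), fluid=UNIT_FLUID)
        times = times_to_percentages(fit, [33.3, 50.0, 66.7, 83.3, 91.7, 95.8])
        assert np.all(np.diff(times) > 0)

    def test_out_of_range_percentage_rejected(self):
        fit = fit_exponential_rise(noiseless_dataset(), fluid=UNIT_FLUID)
        with pytest.raises(DomainError):
            times_to_percentages(fit, [100.0])


class TestTauResistanceRegression:
    def test_published_pairs_reproduce_reported_line(self, table3):
        fit = tau_vs_r_regression([(r, t) for _, r, t in table3])
        assert fit.slope == pytest.approx(0.067, abs=5e-4)
        assert fit.intercept == pytest.approx(-21.01, abs=5e-3)
        # slope read as a manometer area implies a ~2.9 mm bore
        assert fit.implied_bore_diameter * 10 == pytest.approx(2.92, abs=0.01)

    def test_exact_line_recovered(self):
        R = np.array([100.0, 200.0, 300.0])
        fit = tau_vs_r_regression(list(zip(R, 0.1 * R + 3.0)))
        assert fit.slope == pytest.approx(0.1, rel=1e-12)
        assert fit.intercept == pytest.approx(3.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(10.0, 3000.0), st.floats(1.0, 300.0)),
            min_size=3,
            max_size=8,
        )
    )
    def test_matches_normal_equation_oracle(self, pairs):
        R = np.array([p[0] for p in pairs])
        tau = np.array([p[1] for p in pairs])
        if np.ptp(R) < 1e-3:
            return
        # brute-force normal equations (centered form), independent of the
        # lstsq path used by the estimator
        slope = np.sum((R - R.mean()) * (tau - tau.mean())) / np.sum((R - R.mean()) ** 2)
        intercept = tau.mean() - slope * R.mean()
        fit = tau_vs_r_regression(pairs)
        assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)

    def test_identical_resistances_rejected(self):
        with pytest.raises(DomainError):
            tau_vs_r_regression([(100.0, 10.0), (100.0, 12.0)])
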