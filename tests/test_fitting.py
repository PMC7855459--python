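import copy

import numpy as np
import pytest

from batchphys.core import MeasurementSeries
from batchphys.fitting import (
    FitError,
    fit_rates,
    initial_guess,
    model_biomass,
    model_glucose,
    objective,
)
from batchphys.phase import PhaseWindow, detect_window
from batchphys.synthetic import NoiseModel, StrainPreset, simulate_batch


class TestModels:
    def test_zero_growth_is_constant(self):
        t = np.linspace(0, 10, 5)
        np.testing.assert_allclose(model_biomass(0.1, 0.0, t), 0.1)

    def test_exponential_value(self):
        assert model_biomass(0.1, 0.4, 5.0) == pytest.approx(0.1 * np.e**2, rel=1e-12)

    def test_biomass_linear_in_x0(self):
        t = np.linspace(0, 8, 9)
        np.testing.assert_allclose(
            model_biomass(0.2, 0.37, t), 2 * model_biomass(0.1, 0.37, t), rtol=1e-12
        )

    def test_glucose_constant_without_uptake(self):
        t = np.linspace(0, 10, 7)
        np.testing.assert_allclose(model_glucose(55.0, 0.0, 0.4, 0.1, t), 55.0)

    def test_glucose_arithmetic_example(self):
        assert model_glucose(56.25, 5.0, 0.4, 0.1, 0.0) == pytest.approx(55.0)

    def test_glucose_derivative_is_minus_uptake_times_biomass(self):
        # d c/dt = -pi_glc * X(t): Eqs. consistency via central difference
        C, pi, mu, X0, t = 60.0, 4.5, 0.42, 0.12, 3.0
        h = 1e-6
        num = (model_glucose(C, pi, mu, X0, t + h) - model_glucose(C, pi, mu, X0, t - h)) / (2 * h)
        assert num == pytest.approx(-pi * model_biomass(X0, mu, t), rel=1e-6)


class TestFitRates:
    def test_noiseless_recovery(self, zero_noise):
        preset = StrainPreset(X0_true=0.1, mu_true=0.4, pi_glc_true=5.0, glc0=55.0)
        ds = simulate_batch(preset, zero_noise)
        w = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
        f = fit_rates(ds, w)
        assert f.X0 == pytest.approx(0.1, rel=1e-6)
        assert f.mu == pytest.approx(0.4, rel=1e-6)
        assert f.pi_glc == pytest.approx(5.0, rel=1e-6)
        assert f.C == pytest.approx(56.25, rel=1e-6)

    def test_biomass_only_information_matches_log_linear_fit(self, wt_preset, zero_noise):
        """With exact biomass data and glucose weights made negligible,
        mu and X0 must equal the closed-form log-linear regression of
        the biomass series alone."""
        noise = NoiseModel(rel_sd_biomass=0.0, rel_sd_glucose=0.08,
                           abs_sd_gas_volpct=0.0, seed=13)
        ds = simulate_batch(wt_preset, noise)
        ds.glucose.sds = ds.glucose.sds * 1e8  # glucose carries no weight
        w = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
        bio = ds.biomass.window(w.t_start, w.t_end)
        slope, intercept = np.polyfit(bio.times, np.log(bio.values), 1)
        f = fit_rates(ds, w)
        assert f.mu == pytest.approx(slope, rel=1e-6)
        assert f.X0 == pytest.approx(np.exp(intercept), rel=1e-6)

    def test_sse_matches_refined_grid_search(self):
        """Brute-force oracle: zooming 4-D grid search around its own
        best point reaches the same weighted SSE as the optimizer."""
        rng = np.random.default_rng(11)
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        X0_t, mu_t, pi_t, C_t = 0.1, 0.4, 5.0, 56.25
        bio_true = model_biomass(X0_t, mu_t, t)
        glc_true = model_glucose(C_t, pi_t, mu_t, X0_t, t)
        bio = MeasurementSeries(t, bio_true * (1 + 0.05 * rng.normal(size=5)),
                                0.05 * bio_true, "biomass_cdw")
        glc = MeasurementSeries(t, glc_true + 0.5 * rng.normal(size=5),
                                np.full(5, 0.5), "glucose")
        from batchphys.core import BatchDataset, GasConditions

        gas_dummy = MeasurementSeries(t, np.zeros(5), np.full(5, 0.02), "co2_out")
        ds = BatchDataset(bio, glc, gas_dummy, gas_dummy, GasConditions(F=0.06), 1.0)
        w = PhaseWindow(0.0, 4.0, n_points_in_window=5)
        f = fit_rates(ds, w)

        # zooming grid search, 9 points/dim, independent of the optimizer:
        # recenter on the incumbent each pass, shrink only while the
        # incumbent is interior to the box, expand when it hits an edge
        center = initial_guess(bio, glc)
        width = np.abs(center) * 0.5 + 1e-3
        best = np.inf
        for _ in range(120):
            axes = [np.linspace(c - h, c + h, 9) for c, h in zip(center, width)]
            grids = np.meshgrid(*axes, indexing="ij")
            P = np.stack([g.ravel() for g in grids], axis=1)
            ok = (P[:, 0] > 0) & (P[:, 1] > 0) & (P[:, 2] >= 0)
            P = P[ok]
            Xm = P[:, [0]] * np.exp(P[:, [1]] * t)
            rb = (bio.values - Xm) / bio.sds
            Gm = P[:, [3]] - (P[:, [2]] / P[:, [1]]) * P[:, [0]] * np.exp(P[:, [1]] * t)
            rg = (glc.values - Gm) / glc.sds
            sse = (rb**2).sum(axis=1) + (rg**2).sum(axis=1)
            k = int(np.argmin(sse))
            best, incumbent = float(sse[k]), P[k]
            on_edge = np.any(
                np.isclose(np.abs(incumbent - center), width, rtol=1e-9)
            )
            center = incumbent
            width = width * (1.6 if on_edge else 0.5)
        assert f.sse == pytest.approx(best, abs=1e-6)

    def test_descent_from_starting_point(self, noisy_dataset):
        ds = noisy_dataset
        w = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
        bio = ds.biomass.window(w.t_start, w.t_end)
        glc = ds.glucose.window(w.t_start, w.t_end)
        start = initial_guess(bio, glc)
        f = fit_rates(ds, w)
        assert f.sse <= objective(start, bio, glc) + 1e-12

    def test_sd_rescaling_leaves_argmin_unchanged(self, noisy_dataset):
        ds = copy.deepcopy(noisy_dataset)
        w = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
        f1 = fit_rates(ds, w)
        k = 3.0
        ds.biomass.sds = ds.biomass.sds * k
        ds.glucose.sds = ds.glucose.sds * k
        f2 = fit_rates(ds, w)
        for a, b in [(f1.X0, f2.X0), (f1.mu, f2.mu), (f1.pi_glc, f2.pi_glc), (f1.C, f2.C)]:
            assert b == pytest.approx(a, rel=1e-6)
        assert f2.sse == pytest.approx(f1.sse / k**2, rel=1e-6)

    def test_time_shift_equivariance(self, noisy_dataset):
        ds = copy.deepcopy(noisy_dataset)
        w = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
        f1 = fit_rates(ds, w)
        delta = 2.0
        for s in (ds.biomass, ds.glucose, ds.offgas_o2, ds.offgas_co2):
            s.times = s.times + delta
        w2 = PhaseWindow(w.t_start + delta, w.t_end + delta,
                         n_points_in_window=w.n_points_in_window)
        f2 = fit_rates(ds, w2)
        assert f2.mu == pytest.approx(f1.mu, rel=1e-6)
        assert f2.pi_glc == pytest.approx(f1.pi_glc, rel=1e-6)
        assert f2.X0 == pytest.approx(f1.X0 * np.exp(-f1.mu * delta), rel=1e-6)

    def test_too_few_points_raises(self, noisy_dataset):
        with pytest.raises(FitError, match=">= 4"):
            fit_rates(noisy_dataset, PhaseWindow(0.0, 0.6))

    def test_median_recovery_error_below_three_percent(self):
        """Parameter recovery at the default noise level over seeds."""
        errs_mu, errs_pi = [], []
        preset = StrainPreset()
        for seed in range(50):
            ds = simulate_batch(preset, NoiseModel(seed=seed))
            w = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
            f = fit_rates(ds, w)
            errs_mu.append(abs(f.mu - preset.mu_true) / preset.mu_true)
            errs_pi.append(abs(f.pi_glc - preset.pi_glc_true) / preset.pi_glc_true)
        assert np.median(errs_mu) <= 0.03
        assert np.median(errs_pi) <= 0.03
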