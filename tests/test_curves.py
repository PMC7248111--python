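"""Drying-curve analysis: rates, normalisation, plateau, empirical fits."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import bloodpool as bp
from bloodpool.curves import mass_area_model


def make_record(times, masses=None, total=None, wet=None, geometry=None):
    return bp.DryingRecord(
        times=np.asarray(times, float),
        masses=None if masses is None else np.asarray(masses, float),
        total_areas=None if total is None else np.asarray(total, float),
        wet_areas=None if wet is None else np.asarray(wet, float),
        geometry=geometry,
    )


class TestDryingRecord:
    def test_requires_a_channel(self):
        with pytest.raises(bp.InputError):
            make_record([0, 60, 120])

    def test_rejects_non_monotone_times(self):
        with pytest.raises(bp.InputError):
            make_record([0, 120, 60], masses=[3e-3, 2e-3, 1e-3])

    def test_rejects_wet_above_total(self):
        with pytest.raises(bp.InputError):
            make_record([0, 60], total=[1e-3, 1e-3], wet=[1.1e-3, 9e-4])

    def test_flags_mass_rise(self):
        rec = make_record([0, 60, 120, 180], masses=[3e-3, 2.5e-3, 2.8e-3, 2.0e-3])
        assert "non-monotone-mass" in rec.flags


class TestWaterFraction:
    def test_endpoints_and_midpoint(self, fluid):
        m_i = 4e-3
        rec = make_record(
            [0, 100, 200],
            masses=[m_i, 0.615 * m_i, fluid.residual_mass_fraction * m_i],
        )
        wf = bp.water_fraction_left(rec, fluid)
        assert wf[0] == pytest.approx(1.0)
        assert wf[1] == pytest.approx(0.5)
        assert wf[2] == pytest.approx(0.0, abs=1e-12)

    def test_clipped_below_residual(self, fluid):
        rec = make_record([0, 100], masses=[4e-3, 0.1 * 4e-3])
        assert bp.water_fraction_left(rec, fluid)[-1] == 0.0


class TestEvaporationRate:
    def test_linear_mass_loss_constant_area(self, fluid):
        c, area = 2e-8, 3e-3
        t = np.linspace(0, 5000, 21)
        rec = make_record(t, masses=5e-3 - c * t, total=np.full_like(t, area))
        rate = bp.evaporation_rate(rec, basis="total", fluid=fluid)
        assert rate.rates == pytest.approx(np.full(19, c / area), rel=1e-12)

    def test_two_point_record(self, fluid):
        rec = make_record([0, 600], masses=[5e-3, 4.4e-3], total=[3e-3, 3e-3])
        rate = bp.evaporation_rate(rec, fluid=fluid)
        assert len(rate.rates) == 1
        assert rate.rates[0] == pytest.approx(0.6e-3 / (600 * 3e-3), rel=1e-12)

    def test_wet_basis_recovers_generating_flux(self):
        """Constant wet-area flux in, constant rate back out (FD oracle)."""
        sc = bp.PoolScenario(initial_mass=2e-3, flux_basis="wet", seed=5)
        sim = bp.simulate_drying(sc, dt=2.0, t_max=3000.0)
        rate = bp.evaporation_rate(sim.truth, basis="wet")
        assert rate.rates == pytest.approx(np.full_like(rate.rates, sim.jstar), rel=1e-6)

    def test_requires_mass_channel(self):
        rec = make_record([0, 60], wet=[1e-3, 9e-4], total=[1e-3, 1e-3])
        with pytest.raises(bp.InputError):
            bp.evaporation_rate(rec)


class TestNormalize:
    def test_endpoints(self, default_sim):
        norm = bp.normalize_record(default_sim.truth)
        assert norm["time"][0] == 0.0
        assert norm["time"][-1] == 1.0
        assert norm["mass"][0] == pytest.approx(1.0)
        assert norm["wet_area"][0] == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = np.linspace(0, 1000, 11)
        m = np.linspace(5e-3, 2e-3, 11)
        a = np.linspace(3e-3, 3e-3, 11)
        r1 = make_record(t, masses=m, total=a, wet=a * np.linspace(1, 0.2, 11))
        r2 = make_record(t * 7.0, masses=m * 3.0, total=a * 2.0, wet=2 * a * np.linspace(1, 0.2, 11))
        n1, n2 = bp.normalize_record(r1), bp.normalize_record(r2)
        for key in n1:
            assert n1[key] == pytest.approx(n2[key], rel=1e-12)


class TestWeightedRateSeries:
    def test_flat_at_generating_diffusion(self, env, fluid):
        sc = bp.PoolScenario(initial_mass=3e-3, flux_basis="wet", seed=9)
        sim = bp.simulate_drying(sc, dt=60.0, t_max=20000.0)
        d = bp.weighted_rate_series(
            sim.true_rate_series(), sim.geometry, env, fluid
        )
        drying = sim.truth.masses > fluid.residual_mass_fraction * sc.initial_mass
        assert d[drying] == pytest.approx(
            np.full(int(drying.sum()), sc.model.d_blood), rel=1e-12
        )

    def test_two_shapes_collapse_identically(self, env, fluid):
        """Pools of different L* generated from one D weight to the same series."""
        vals = []
        for irr, seed in [(0.0, 1), (0.4, 2)]:
            sc = bp.PoolScenario(
                initial_mass=4e-3, shape_irregularity=irr, flux_basis="wet", seed=seed
            )
            sim = bp.simulate_drying(sc, dt=120.0, t_max=10000.0)
            d = bp.weighted_rate_series(sim.true_rate_series(), sim.geometry, env, fluid)
            vals.append(d[:50])
        spread = np.abs(vals[0] - vals[1]) / 1e-9
        assert spread.max() < 1e-9

    def test_rejects_total_basis(self, env, fluid, default_sim):
        rate = bp.evaporation_rate(default_sim.truth, basis="total")
        with pytest.raises(bp.InputError):
            bp.weighted_rate_series(rate, default_sim.geometry, env, fluid)


class TestPlateau:
    def test_flat_noiseless(self):
        wf = np.linspace(0.95, 0.05, 40)
        est = bp.estimate_plateau(np.full(40, 2.5e-9), wf)
        assert est.value == 2.5e-9
        assert est.spread == 0.0

    def test_noisy_value_within_noise_over_sqrt_n(self, rng):
        wf = np.linspace(0.99, 0.01, 400)
        noise = 1e-10
        vals = 1e-9 + rng.normal(0, noise, 400)
        est = bp.estimate_plateau(vals, wf)
        # median of ~200 in-window points: sd ~ 1.25 * noise / sqrt(n)
        assert abs(est.value - 1e-9) < 5 * 1.25 * noise / np.sqrt(est.n_points)

    def test_excursions_outside_window_ignored(self):
        wf = np.linspace(1.0, 0.0, 100)
        vals = np.full(100, 1e-9)
        vals[wf > 0.85] = 5e-9  # early dip/spike
        vals[wf < 0.35] = 1e-11  # biased tail
        est = bp.estimate_plateau(vals, wf)
        assert est.value == 1e-9
        assert est.spread == 0.0

    def test_empty_window_raises(self):
        with pytest.raises(bp.EstimationError):
            bp.estimate_plateau(np.ones(10), np.full(10, 0.95))


class TestMassAreaFit:
    def test_exact_recovery_of_calibration_constants(self):
        a = np.linspace(0.0, 1.0, 60)
        m = mass_area_model(a, 0.78, 0.16)
        fit = bp.fit_mass_area(a, m)
        assert fit.alpha == pytest.approx(0.78, rel=1e-4)
        assert fit.beta == pytest.approx(0.16, rel=1e-4)
        assert fit.residual_norm < 1e-10

    def test_anchor_point(self):
        # A/A_i = 1 maps to m/m_i = 1 regardless of parameters
        for alpha, beta in [(0.3, 0.5), (0.78, 0.16), (0.9, 1.5)]:
            assert mass_area_model(np.array([1.0]), alpha, beta)[0] == 1.0

    def test_noisy_recovery_within_fit_uncertainty(self, rng):
        a = np.linspace(0.05, 1.0, 80)
        m = mass_area_model(a, 0.5, 0.5) + rng.normal(0, 0.005, 80)
        fit = bp.fit_mass_area(a, m)
        popt, pcov = curve_fit(
            mass_area_model, a, m, p0=(0.8, 0.2), bounds=([1e-9, 1e-9], [1 - 1e-9, 2.0])
        )
        sd = np.sqrt(np.diag(pcov))
        assert abs(fit.alpha - 0.5) < 4 * sd[0]
        assert abs(fit.beta - 0.5) < 4 * sd[1]

    def test_preconditions(self):
        with pytest.raises(bp.InputError):
            bp.fit_mass_area([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        with pytest.raises(bp.InputError):
            bp.fit_mass_area(np.linspace(0.5, 0.6, 10), np.linspace(0.4, 0.5, 10))


class TestShapeLinearFit:
    def test_exact_recovery_of_reported_line(self):
        """Points on J*/L* = 1.72e-7 theta + 1.79e-6 are recovered exactly."""
        theta = np.linspace(0.3, 1.2, 12)
        lstar = np.linspace(5.0, 15.0, 12)
        jstar = lstar * (1.72e-7 * theta + 1.79e-6)
        fit = bp.fit_shape_linear(theta, jstar, lstar)
        assert fit.slope == pytest.approx(1.72e-7, rel=1e-10)
        assert fit.intercept == pytest.approx(1.79e-6, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_design_raises(self):
        with pytest.raises(bp.EstimationError):
            bp.fit_shape_linear([0.5, 0.5, 0.5], [1e-6, 2e-6, 3e-6], [5, 5, 5])

    def test_needs_three_pools(self):
        with pytest.raises(bp.InputError):
            bp.fit_shape_linear([0.4, 0.6], [1e-6, 2e-6], [5, 6])
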