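"""Unit and property tests for the single-pool drying formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bloodpool as bp


class TestVolumeHeightMass:
    def test_volume_from_mass(self, fluid):
        assert bp.volume_from_mass(5.24e-3, fluid) == pytest.approx(4.9434e-6, rel=1e-4)

    def test_volume_identity(self, fluid):
        assert bp.volume_from_mass(fluid.density_rho, fluid) == pytest.approx(1.0)

    def test_volume_rejects_nonpositive_mass(self, fluid):
        with pytest.raises(bp.InputError):
            bp.volume_from_mass(0.0, fluid)

    def test_height_from_volume_area(self):
        # matches the mean tile pool height (~1.44 mm)
        assert bp.height_from_volume_area(4.94e-6, 3.43e-3) == pytest.approx(
            1.4402e-3, rel=1e-4
        )
        assert bp.height_from_volume_area(2.0, 2.0) == 1.0
        assert bp.height_from_volume_area(0.0, 1.0) == 0.0

    def test_height_rejects_zero_area(self):
        with pytest.raises(bp.InputError):
            bp.height_from_volume_area(1e-6, 0.0)

    def test_mass_from_geometry(self, fluid):
        geom = bp.PoolGeometry(
            total_area=2.5e-3, perimeter=0.20, height=1.44e-3, initial_mass=3.816e-3
        )
        assert bp.mass_from_geometry(geom, fluid) == pytest.approx(3.816e-3, rel=1e-6)

    def test_mass_volume_height_identity_chain(self, fluid):
        geom = bp.PoolGeometry(
            total_area=3e-3, perimeter=0.22, height=1.2e-3, initial_mass=1.0
        )
        m = bp.mass_from_geometry(geom, fluid)
        v = bp.volume_from_mass(m, fluid)
        assert bp.height_from_volume_area(v, geom.total_area) == pytest.approx(
            geom.height, rel=1e-12
        )


class TestShapeFactor:
    def test_hand_value(self):
        geom = bp.PoolGeometry(
            total_area=2.5e-3, perimeter=0.20, height=1.44e-3, initial_mass=3.8e-3
        )
        assert bp.shape_factor(geom) == pytest.approx(8.6806, rel=1e-4)

    def test_unity_when_area_equals_h_times_p(self):
        geom = bp.PoolGeometry(
            total_area=1e-2, perimeter=1.0, height=1e-2, initial_mass=1e-2
        )
        assert bp.shape_factor(geom) == pytest.approx(1.0)

    @pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
    def test_isotropic_rescaling_law(self, s):
        # A -> s^2 A, P -> s P at fixed h multiplies L* by s
        g1 = bp.PoolGeometry(2.5e-3, 0.20, 1.44e-3, 3.8e-3)
        g2 = bp.PoolGeometry(s**2 * 2.5e-3, s * 0.20, 1.44e-3, 3.8e-3)
        assert bp.shape_factor(g2) == pytest.approx(s * bp.shape_factor(g1), rel=1e-12)


class TestContactAngle:
    def test_hand_value(self, fluid, constants):
        geom = bp.PoolGeometry(2.5e-3, 0.20, 1.44e-3, 5.24e-3)
        assert bp.contact_angle(geom, fluid, constants) == pytest.approx(
            0.86371, rel=1e-4
        )

    def test_flat_film_limit(self, fluid, constants):
        geom = bp.PoolGeometry(2.5e-3, 0.20, 1.44e-3, 1e-9)
        assert bp.contact_angle(geom, fluid, constants) < 1e-3

    def test_right_angle_at_unit_argument(self, constants):
        # choose m so that g m^2 / (2 gamma rho A^2) = 1 -> theta = pi/2
        fluid = bp.FluidProperties()
        area = 2.5e-3
        m = math.sqrt(
            2 * fluid.surface_tension_gamma * fluid.density_rho * area**2 / constants.gravity_g
        )
        geom = bp.PoolGeometry(area, 0.20, 1.44e-3, m)
        assert bp.contact_angle(geom, fluid, constants) == pytest.approx(math.pi / 2)

    def test_out_of_range_raises_not_clamps(self, fluid, constants):
        # heaped far beyond the puddle regime
        geom = bp.PoolGeometry(1e-4, 0.04, 1.44e-3, 4.9e-2)
        with pytest.raises(bp.ApproximationRangeError):
            bp.contact_angle(geom, fluid, constants)

    def test_monotone_in_mass(self, fluid, constants):
        masses = np.linspace(1e-3, 8e-3, 20)
        angles = [
            bp.contact_angle(bp.PoolGeometry(2.5e-3, 0.20, 1.44e-3, m), fluid, constants)
            for m in masses
        ]
        assert np.all(np.diff(angles) > 0)


class TestSaturationVapourPressure:
    def test_steam_table_20C(self):
        assert bp.saturation_vapour_pressure(293.15) == pytest.approx(2338.3, rel=2e-3)

    def test_boiling_point_consistency(self):
        assert bp.saturation_vapour_pressure(373.15) == pytest.approx(101325, rel=0.01)

    def test_monotone(self):
        temps = np.linspace(274.0, 372.0, 50)
        p = [bp.saturation_vapour_pressure(t) for t in temps]
        assert np.all(np.diff(p) > 0)

    @pytest.mark.parametrize("bad", [250.0, 400.0])
    def test_domain(self, bad):
        with pytest.raises(bp.ModelDomainError):
            bp.saturation_vapour_pressure(bad)


class TestKnudsenLayer:
    def test_hand_value(self, fluid, constants):
        env = bp.EnvironmentConditions(296.15, 0.20, 101325.0)
        assert bp.knudsen_layer(env, fluid, constants) == pytest.approx(
            1.6985e-7, rel=1e-4
        )

    def test_pressure_and_temperature_proportionality(self, fluid, constants):
        env = bp.EnvironmentConditions(296.15, 0.20, 101325.0)
        lk = bp.knudsen_layer(env, fluid, constants)
        env2 = bp.EnvironmentConditions(296.15, 0.20, 2 * 101325.0)
        assert bp.knudsen_layer(env2, fluid, constants) == pytest.approx(lk / 2)
        env3 = bp.EnvironmentConditions(2 * 296.15, 0.20, 101325.0)
        assert bp.knudsen_layer(env3, fluid, constants) == pytest.approx(2 * lk)

    @pytest.mark.parametrize("d_angstrom", [2.5, 2.75, 3.0])
    def test_ambient_magnitude(self, constants, d_angstrom):
        fluid = bp.FluidProperties(water_molecular_diameter_d=d_angstrom * 1e-10)
        env = bp.EnvironmentConditions(296.15, 0.20, 101325.0)
        assert 1e-7 <= bp.knudsen_layer(env, fluid, constants) <= 3e-7


class TestEvaporationRate:
    def test_hand_value(self, fluid, constants):
        env = bp.EnvironmentConditions(293.15, 0.20, 101325.0)
        j = bp.evaporation_rate_from_diffusion(1e-9, 9.0, env, fluid, constants)
        assert j == pytest.approx(3.4265e-5, rel=1e-4)

    def test_shape_factor_scaling(self, env, fluid, constants):
        j1 = bp.evaporation_rate_from_diffusion(1e-9, 4.0, env, fluid, constants)
        j2 = bp.evaporation_rate_from_diffusion(1e-9, 16.0, env, fluid, constants)
        assert j2 == pytest.approx(j1 / 2, rel=1e-12)

    def test_humidity_deficit_flag(self, env, fluid, constants):
        j = bp.evaporation_rate_from_diffusion(1e-9, 9.0, env, fluid, constants)
        jh = bp.evaporation_rate_from_diffusion(
            1e-9, 9.0, env, fluid, constants, use_humidity_deficit=True
        )
        assert jh == pytest.approx(j * (1 - env.relative_humidity), rel=1e-12)

    def test_zero_rate_inverts_to_zero(self, env, fluid, constants):
        assert bp.diffusion_from_evaporation_rate(0.0, 5.0, env, fluid, constants) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        d=st.floats(1e-12, 1e-6),
        lstar=st.floats(1e-2, 1e3),
        t=st.floats(278.0, 370.0),
    )
    def test_forward_inverse_round_trip(self, d, lstar, t):
        env = bp.EnvironmentConditions(t, 0.20, 101325.0)
        fluid = bp.FluidProperties()
        j = bp.evaporation_rate_from_diffusion(d, lstar, env, fluid)
        back = bp.diffusion_from_evaporation_rate(j, lstar, env, fluid)
        assert back == pytest.approx(d, rel=1e-12)


class TestTypesAndUnits:
    def test_constants_immutable_defaults(self, constants):
        assert constants.boltzmann_k == pytest.approx(1.380649e-23)
        assert constants.gas_constant_R == pytest.approx(8.314462618, rel=1e-9)
        with pytest.raises(Exception):
            constants.gravity_g = 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperature": 150.0},
            {"temperature": 296.0, "relative_humidity": 1.5},
            {"temperature": 296.0, "atmospheric_pressure": -1.0},
        ],
    )
    def test_environment_invariants(self, kwargs):
        with pytest.raises(bp.InputError):
            bp.EnvironmentConditions(**kwargs)

    def test_geometry_rejects_isoperimetric_violation(self):
        # a circle of area 1e-2 has P = 0.354; ask for far less
        with pytest.raises(bp.InputError):
            bp.PoolGeometry(total_area=1e-2, perimeter=0.1, height=1e-3, initial_mass=1e-2)

    def test_dimensional_consistency_of_rate(self, fluid, constants):
        """J* must be invariant under a pure change of SI prefix bookkeeping.

        Scaling D (m^2/s) by s^2 and the Knudsen layer by s (via pressure
        1/s) changes J* by exactly s; verified through the formula.
        """
        env = bp.EnvironmentConditions(296.15, 0.2, 101325.0)
        envs = bp.EnvironmentConditions(296.15, 0.2, 101325.0 / 2.0)
        j1 = bp.evaporation_rate_from_diffusion(1e-9, 9.0, env, fluid, constants)
        j2 = bp.evaporation_rate_from_diffusion(1e-9, 9.0, envs, fluid, constants)
        # halving P_a doubles L_k and halves J*
        assert j2 == pytest.approx(j1 / 2, rel=1e-12)
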