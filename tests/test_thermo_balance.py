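"""First-law balance: power, temperature rate, convection, flux, mole balance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celltherm import (
    CellGeometry,
    ThermoEnvironment,
    celsius_to_kelvin,
    convection_coefficient,
    electric_power_sodium,
    heat_outflow,
    inflammation_heat,
    potential_temperature_curve,
    sodium_flux_from_heat,
    sodium_moles,
    temperature_rate,
)

radius = st.floats(min_value=2e-6, max_value=100e-6)
thickness = st.floats(min_value=1e-9, max_value=10e-9)
flux = st.floats(min_value=-10.0, max_value=10.0)
field = st.floats(min_value=-5e7, max_value=5e7).filter(lambda x: abs(x) > 1.0)


class TestGeometry:
    def test_sphere_derived_quantities(self, geometry):
        assert geometry.surface_area == pytest.approx(4 * math.pi * 1e-10, rel=1e-12)
        assert geometry.volume == pytest.approx(4 * math.pi * 1e-15 / 3, rel=1e-12)
        assert geometry.mean_radius == pytest.approx(geometry.radius / 3, rel=1e-12)

    def test_rejects_thick_membrane(self):
        with pytest.raises(ValueError, match="small relative"):
            CellGeometry(radius=10e-6, membrane_thickness=5e-6)

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            CellGeometry(radius=-1e-6, membrane_thickness=4e-9)


class TestElectricPower:
    def test_worked_example(self, geometry):
        """Unit inward flux against the resting field on a 10 µm cell."""
        power = electric_power_sodium(1.0, -1.75e7, geometry)
        assert power == pytest.approx(-8.80e-11, rel=5e-3)

    def test_zero_flux_zero_power(self, geometry):
        assert electric_power_sodium(0.0, -1.75e7, geometry) == 0.0

    def test_doubling_radius_quadruples_power(self):
        small = CellGeometry(10e-6, 4e-9)
        large = CellGeometry(20e-6, 4e-9)
        assert electric_power_sodium(1.0, 1e7, large) == pytest.approx(
            4 * electric_power_sodium(1.0, 1e7, small), rel=1e-12
        )


class TestTemperatureRate:
    def test_worked_example(self, environment, geometry):
        rate = temperature_rate(-8.80e-11, environment, geometry)
        assert rate == pytest.approx(-5.02e-3, rel=5e-3)

    def test_zero_power_zero_rate(self, environment, geometry):
        assert temperature_rate(0.0, environment, geometry) == 0.0

    @given(j=flux, e=field, r=radius, d=thickness)
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_with_power(self, j, e, r, d):
        geom = CellGeometry(r, d)
        env = ThermoEnvironment()
        power = electric_power_sodium(j, e, geom)
        back = temperature_rate(power, env, geom) * env.density * env.specific_heat * geom.volume
        assert back == pytest.approx(power, rel=1e-12, abs=1e-300)


class TestConvection:
    def test_default_coefficient(self, environment):
        """Soft-tissue defaults at ⟨R⟩ = 10/3 µm give ≈ 941 W m⁻² K⁻¹."""
        alpha = convection_coefficient(environment, 10e-6 / 3)
        assert alpha == pytest.approx(941.0, rel=2e-3)

    def test_inverse_mean_radius_scaling(self, environment):
        assert convection_coefficient(environment, 1e-6) == pytest.approx(
            2 * convection_coefficient(environment, 2e-6), rel=1e-12
        )

    def test_zero_reynolds_gives_zero(self):
        env = ThermoEnvironment(reynolds=0.0)
        assert convection_coefficient(env, 1e-6) == 0.0

    def test_rejects_zero_mean_radius(self, environment):
        with pytest.raises(ValueError):
            convection_coefficient(environment, 0.0)


class TestHeatOutflow:
    def test_equilibrium_gives_zero(self, geometry):
        env = ThermoEnvironment(cell_temperature=310.15, bath_temperature=310.15)
        assert heat_outflow(env, geometry) == 0.0

    def test_warm_cell_exports_heat(self, environment, geometry):
        assert heat_outflow(environment, geometry) < 0.0

    def test_linear_in_temperature_difference(self, geometry):
        one = ThermoEnvironment(cell_temperature=310.15 + 0.2)
        two = ThermoEnvironment(cell_temperature=310.15 + 0.4)
        assert heat_outflow(two, geometry) == pytest.approx(
            2 * heat_outflow(one, geometry), rel=1e-12
        )


class TestSodiumFluxFromHeat:
    def test_zero_heat_zero_flux(self, geometry):
        assert sodium_flux_from_heat(0.0, -1.75e7, geometry) == 0.0

    @pytest.mark.parametrize("qdot", [-1e-12, 1e-12])
    @pytest.mark.parametrize("e", [-1.75e7, 1.75e7])
    def test_sign_rule_flux_follows_heat(self, geometry, qdot, e):
        """Heat export implies sodium outflow for either field orientation."""
        j = sodium_flux_from_heat(qdot, e, geometry)
        assert math.copysign(1, j) == math.copysign(1, qdot)

    @given(qdot=st.floats(min_value=-1e-9, max_value=1e-9), e=field,
           r=radius, d=thickness)
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_with_power(self, qdot, e, r, d):
        geom = CellGeometry(r, d)
        j = sodium_flux_from_heat(qdot, e, geom)
        assert electric_power_sodium(j, abs(e), geom) == pytest.approx(
            qdot, rel=1e-12, abs=1e-300
        )

    def test_rejects_zero_field(self, geometry):
        with pytest.raises(ValueError, match="field"):
            sodium_flux_from_heat(-1e-12, 0.0, geometry)


class TestChainEquality:
    @given(delta_t=st.floats(min_value=-1.0, max_value=1.0).filter(lambda x: abs(x) > 1e-4),
           e=field, r=radius, d=thickness)
    @settings(derandomize=True, max_examples=250)
    def test_three_way_identity(self, delta_t, e, r, d):
        """Q̇ = ρcV·dT/dt = J·E·A·d: the three routes agree to 1e-10 relative.

        A consistent state is built from a random cell/bath temperature
        offset: the convective outflow fixes the flux density that sustains
        it, and all three expressions must return the same power.
        """
        geom = CellGeometry(r, d)
        env = ThermoEnvironment(cell_temperature=310.15 + delta_t,
                                bath_temperature=310.15)
        q_conv = heat_outflow(env, geom)
        j = q_conv / (e * geom.surface_area * geom.membrane_thickness)
        power = electric_power_sodium(j, e, geom)
        q_internal = (temperature_rate(power, env, geom)
                      * env.density * env.specific_heat * geom.volume)
        assert power == pytest.approx(q_conv, rel=1e-10, abs=1e-300)
        assert q_internal == pytest.approx(q_conv, rel=1e-10, abs=1e-300)


class TestPotentialTemperatureCurve:
    @pytest.mark.parametrize(
        "t_celsius, expected_mv",
        [(19.0, 3.36), (25.0, 2.27), (31.0, 1.17), (37.4, 0.0)],
    )
    def test_reported_decreases(self, sodium, t_celsius, expected_mv):
        """Potential decrease below the 37.4 °C operating point."""
        (dphi,) = potential_temperature_curve(
            [celsius_to_kelvin(t_celsius)], sodium, reference_temperature=310.55
        )
        assert dphi * 1e3 == pytest.approx(expected_mv, abs=5e-3)

    def test_affine_with_expected_slope(self, sodium):
        """Slope −(R/F)·ln(150/18) ≈ −1.827e-4 V/K, constant across the range."""
        temps = [celsius_to_kelvin(t) for t in (19.0, 25.0, 31.0, 37.0)]
        values = potential_temperature_curve(temps, sodium)
        slopes = [
            (values[i + 1] - values[i]) / (temps[i + 1] - temps[i])
            for i in range(len(values) - 1)
        ]
        for s in slopes:
            assert s == pytest.approx(-1.827e-4, rel=1e-3)

    def test_strictly_decreasing_in_temperature(self, sodium):
        temps = [celsius_to_kelvin(t) for t in (19, 24, 29, 34, 39)]
        values = potential_temperature_curve(temps, sodium)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_rejects_unphysical_temperature(self, sodium):
        with pytest.raises(ValueError):
            potential_temperature_curve([450.0], sodium)


class TestInflammationHeat:
    def test_no_excursion_no_heat(self, environment, geometry):
        assert inflammation_heat(environment, geometry, environment.cell_temperature) == 0.0

    def test_worked_example(self, environment, geometry):
        """0.4 K excursion on a 10 µm cell stores ≈ 7.01 nJ."""
        q = inflammation_heat(environment, geometry, environment.cell_temperature + 0.4)
        assert q == pytest.approx(7.01e-9, rel=2e-3)

    def test_linear_in_excursion_and_volume(self, environment):
        small = CellGeometry(10e-6, 4e-9)
        big = CellGeometry(10e-6 * 2 ** (1 / 3), 4e-9)
        q1 = inflammation_heat(environment, small, environment.cell_temperature + 0.2)
        q2 = inflammation_heat(environment, small, environment.cell_temperature + 0.4)
        q3 = inflammation_heat(environment, big, environment.cell_temperature + 0.2)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)
        assert q3 == pytest.approx(2 * q1, rel=1e-9)

    def test_rejects_subnormal_high_temperature(self, environment, geometry):
        with pytest.raises(ValueError, match="excess"):
            inflammation_heat(environment, geometry, environment.cell_temperature - 0.1)


class TestSodiumMoles:
    def test_no_excursion_no_transfer(self, environment, geometry):
        result = sodium_moles(environment, geometry, environment.cell_temperature)
        assert result.moles == 0.0

    def test_worked_example(self, environment, geometry):
        """0.4 K, +56 mV, −261.89 kJ/mol, ΔpH=0 → ≈ 2.62e-14 mol."""
        result = sodium_moles(environment, geometry,
                              environment.cell_temperature + 0.4)
        assert result.moles == pytest.approx(2.62e-14, rel=5e-3)
        assert result.heat == pytest.approx(7.01e-9, rel=2e-3)

    def test_linear_in_excursion(self, environment, geometry):
        t = environment.cell_temperature
        one = sodium_moles(environment, geometry, t + 0.2).moles
        two = sodium_moles(environment, geometry, t + 0.4).moles
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_monotone_in_high_temperature(self, environment, geometry):
        t = environment.cell_temperature
        values = [sodium_moles(environment, geometry, t + dt).moles
                  for dt in (0.1, 0.2, 0.5, 1.0)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_zero_denominator_diagnostic_names_terms(self, environment, geometry):
        with pytest.raises(ValueError) as err:
            sodium_moles(environment, geometry,
                         environment.cell_temperature + 0.4,
                         delta_phi_na=0.0, delta_h=0.0, delta_ph=0.0)
        message = str(err.value)
        assert "delta_phi" in message and "delta_h" in message and "delta_pH" in message
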