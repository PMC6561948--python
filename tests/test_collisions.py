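"""Collision physics: number density, hydrodynamics, Hertz contact, MC ensemble."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nanostress.collisions import (
    CellMechanics,
    FlowField,
    RodPopulation,
    calibrated_stiff_bound,
    collision_rate,
    hertz_impact,
    hertz_static_contact,
    pressure_distribution_mc,
    reference_ratios,
    rod_number_density,
    soft_contact_bound,
    stirred_flask_hydrodynamics,
)


class TestRodNumberDensity:
    def test_printed_geometry_gives_1p26e17_per_m3(self):
        # hand calculation: rod volume 1.415e-21 m^3, rod mass 7.93e-18 kg
        rods = RodPopulation()
        assert rods.mean_volume == pytest.approx(1.415e-21, rel=1e-3)
        assert rods.mean_mass == pytest.approx(7.93e-18, rel=1e-3)
        assert rod_number_density(rods) == pytest.approx(1.26e17, rel=1e-2)

    def test_linear_in_concentration(self):
        n1 = rod_number_density(RodPopulation(mass_concentration=1.0))
        n2 = rod_number_density(RodPopulation(mass_concentration=2.0))
        n0 = rod_number_density(RodPopulation(mass_concentration=0.0))
        assert n2 == pytest.approx(2 * n1, rel=1e-12)
        assert n0 == 0.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            RodPopulation(length_mean=-1e-9)
        with pytest.raises(ValueError):
            RodPopulation(material_density=0.0)
        with pytest.raises(ValueError):
            RodPopulation(tip_radius_max=50e-9)  # > width/2


class TestHydrodynamics:
    def test_shaken_flask_reynolds_order_1e4(self):
        h = stirred_flask_hydrodynamics(FlowField())
        assert h["reynolds"] == pytest.approx(1.2e4, rel=0.05)
        assert 1e4 <= h["reynolds"] < 1e5

    def test_orbital_tip_speed_in_characteristic_band(self):
        h = stirred_flask_hydrodynamics(FlowField())
        v_tip = h["velocity_scales"]["v_tip"]
        assert v_tip == pytest.approx(math.pi * 0.05 * 200 / 60, rel=1e-12)
        assert 0.2 <= v_tip <= 1.8

    def test_no_rotation_is_degenerate(self):
        h = stirred_flask_hydrodynamics(FlowField(rotation_rate=0.0))
        assert h["reynolds"] == 0.0
        assert h["velocity_scales"]["v_tip"] == 0.0

    def test_zero_viscosity_rejected(self):
        with pytest.raises(ValueError):
            FlowField(fluid_viscosity=0.0)


class TestCollisionRate:
    def test_printed_regime_1e5_per_second(self):
        n = rod_number_density(RodPopulation())
        rate = collision_rate(n, CellMechanics().cross_section, 0.25)
        assert rate == pytest.approx(9.9e4, rel=0.02)

    def test_exact_product(self):
        assert collision_rate(1e17, 1e-12, 1.0) == pytest.approx(1e5, rel=1e-12)

    def test_zero_velocity_zero_rate_and_negative_rejected(self):
        assert collision_rate(1e17, 1e-12, 0.0) == 0.0
        with pytest.raises(ValueError):
            collision_rate(-1.0, 1e-12, 1.0)

    @given(
        n=st.floats(1e10, 1e20),
        sigma=st.floats(1e-14, 1e-10),
        v=st.floats(1e-3, 10.0),
        k=st.floats(0.1, 10.0),
    )
    def test_homogeneous_degree_one_in_each_factor(self, n, sigma, v, k):
        base = collision_rate(n, sigma, v)
        assert collision_rate(k * n, sigma, v) == pytest.approx(k * base, rel=1e-10)
        assert collision_rate(n, k * sigma, v) == pytest.approx(k * base, rel=1e-10)
        assert collision_rate(n, sigma, k * v) == pytest.approx(k * base, rel=1e-10)


class TestHertzStatic:
    def test_hand_evaluated_nanoindentation(self):
        # a = (3FR/4E*)^(1/3) with F=10 nN, R=2 nm, E*=3 GPa
        e = hertz_static_contact(10e-9, 2e-9, 3e9)
        assert e.contact_radius == pytest.approx(1.71e-9, rel=1e-2)
        assert e.pressure_mean == pytest.approx(1.09e9, rel=1e-2)
        assert e.pressure_peak == pytest.approx(1.63e9, rel=1e-2)

    def test_zero_force_zero_contact(self):
        e = hertz_static_contact(0.0, 2e-9, 3e9)
        assert e.contact_radius == 0.0 and e.pressure_mean == 0.0 and e.pressure_peak == 0.0

    def test_force_power_law_exponents(self):
        e1 = hertz_static_contact(1e-9, 5e-9, 1e9)
        e8 = hertz_static_contact(8e-9, 5e-9, 1e9)
        assert e8.contact_radius == pytest.approx(2 * e1.contact_radius, rel=1e-10)
        assert e8.pressure_mean == pytest.approx(2 * e1.pressure_mean, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hertz_static_contact(1e-9, 0.0, 1e9)
        with pytest.raises(ValueError):
            hertz_static_contact(-1e-9, 1e-9, 1e9)


class TestHertzImpact:
    def test_soft_contact_hand_evaluation(self):
        e = hertz_impact(7.93e-18, 1.0, 10e-9, 33e6)
        assert e.indentation_max == pytest.approx(5.5e-9, rel=0.01)
        assert e.force_max == pytest.approx(1.8e-9, rel=0.01)
        assert e.pressure_mean == pytest.approx(10e6, rel=0.05)
        assert e.pressure_peak == pytest.approx(16e6, rel=0.05)
        assert not e.hertz_valid  # delta/R = 0.55 >> 0.1, flagged but reported

    def test_stiff_sharp_contact_reaches_gpa_regime(self):
        e = hertz_impact(7.93e-18, 1.8, 2e-9, 20e9)
        assert e.pressure_peak == pytest.approx(8.7e9, rel=0.01)

    def test_zero_velocity_all_zero_event(self):
        e = hertz_impact(7.93e-18, 0.0, 10e-9, 33e6)
        assert e.indentation_max == 0.0 and e.force_max == 0.0 and e.pressure_peak == 0.0
        assert e.hertz_valid

    def test_closed_form_self_consistency(self):
        # F = (4/3) E* sqrt(R) delta^1.5, a^2 = R delta, p0 = 1.5 p_mean
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = 10 ** rng.uniform(-18, -16)
            v = rng.uniform(0.05, 2.0)
            r = 10 ** rng.uniform(-9, -7.4)
            e_star = 10 ** rng.uniform(7, 10.3)
            ev = hertz_impact(m, v, r, e_star)
            assert ev.force_max == pytest.approx(
                (4 / 3) * e_star * math.sqrt(r) * ev.indentation_max**1.5, rel=1e-10
            )
            assert ev.contact_radius**2 == pytest.approx(r * ev.indentation_max, rel=1e-10)
            assert ev.pressure_peak == pytest.approx(1.5 * ev.pressure_mean, rel=1e-10)

    def test_indentation_matches_impact_ode_oracle(self):
        """Numerically integrating m*d2(delta) = -(4/3)E*sqrt(R)*delta^1.5
        recovers the closed-form maximum indentation within 0.5%."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = 10 ** rng.uniform(-18, -16)
            v = rng.uniform(0.1, 2.0)
            r = 10 ** rng.uniform(-9, -7.4)
            e_star = 10 ** rng.uniform(7, 10.3)
            closed = hertz_impact(m, v, r, e_star).indentation_max
            k = (4 / 3) * e_star * math.sqrt(r)

            def rhs(t, y):
                return [y[1], -(k / m) * max(y[0], 0.0) ** 1.5]

            # integrate until rebound; contact time ~ 2.94 * delta_max / v
            t_end = 5.0 * closed / v
            sol = solve_ivp(rhs, (0, t_end), [0.0, v], rtol=1e-10, atol=1e-30, dense_output=True)
            numeric = sol.y[0].max()
            assert numeric == pytest.approx(closed, rel=5e-3)

    def test_peak_pressure_monotonicity(self):
        base = hertz_impact(7.93e-18, 1.0, 10e-9, 1e9).pressure_peak
        assert hertz_impact(7.93e-18, 1.5, 10e-9, 1e9).pressure_peak > base
        assert hertz_impact(7.93e-18, 1.0, 10e-9, 2e9).pressure_peak > base
        assert hertz_impact(7.93e-18, 1.0, 20e-9, 1e9).pressure_peak < base


class TestPressureEnsemble:
    def test_default_ensemble_spans_printed_range(self):
        s = pressure_distribution_mc(n_samples=100_000, seed=1)
        assert s.pressure_max <= 10e9  # printed ceiling
        assert s.pressure_max > 1e9  # GPa regime
        assert math.log10(s.pressure_max / s.pressure_min) >= 4.0  # >= 4 decades

    def test_seed_reproducibility_bitwise(self):
        a = pressure_distribution_mc(n_samples=5000, seed=42)
        b = pressure_distribution_mc(n_samples=5000, seed=42)
        assert a == b

    def test_degenerate_ensemble_equals_single_impact(self):
        rods = RodPopulation(length_sd=0.0, width_sd=0.0, tip_radius_min=10e-9, tip_radius_max=10e-9)
        s = pressure_distribution_mc(
            rods=rods,
            velocity_range=(1.0, 1.0),
            stiffness_range=(33e6, 33e6),
            theta_range=(0.0, 0.0),
            n_samples=1,
            seed=0,
        )
        expected = hertz_impact(rods.mean_mass, 1.0, 10e-9, 33e6)
        assert s.pressure_max == pytest.approx(expected.pressure_peak, rel=1e-10)
        assert s.pressure_min == pytest.approx(expected.pressure_peak, rel=1e-10)

    def test_ensemble_extremes_within_analytic_envelope(self):
        """Sample max must not exceed the head-on/max-v/min-R/max-E*/max-mass
        corner; sample min must not fall below the grazing limit (-> 0)."""
        rods = RodPopulation()
        summary, samples = pressure_distribution_mc(n_samples=20_000, seed=3, return_samples=True)
        corner = hertz_impact(
            float(samples["rod_mass_kg"].max()),
            1.8,
            rods.tip_radius_min,
            float(samples["e_star_pa"].max()),
        ).pressure_peak
        assert 0.0 < summary.pressure_min
        assert summary.pressure_max <= corner

    def test_percentiles_ordered_between_extremes(self):
        s = pressure_distribution_mc(n_samples=10_000, seed=9)
        values = [s.percentiles[q] for q in sorted(s.percentiles)]
        assert values == sorted(values)
        assert s.pressure_min <= values[0] and values[-1] <= s.pressure_max
        assert 0.0 <= s.fraction_exceeding_turgor <= 1.0

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            pressure_distribution_mc(velocity_range=(0.0, 0.0), n_samples=10)
        with pytest.raises(ValueError):
            pressure_distribution_mc(n_samples=0)


class TestReferenceRatios:
    def test_ceiling_is_400x_young_modulus(self):
        r = reference_ratios(10e9, CellMechanics())
        assert r["ratio_to_young"] == pytest.approx(400.0, rel=1e-12)

    def test_turgor_scale_pressure(self):
        assert reference_ratios(0.3e6)["ratio_to_turgor"] == pytest.approx(1.0)
        assert reference_ratios(0.1e6)["ratio_to_young"] == pytest.approx(0.004)


def test_stiffness_bounds_bracket_printed_pressure_range():
    """The soft bound reproduces E_cell/(1-nu^2) ~ 33 MPa; the calibrated
    stiff bound puts the hardest plausible impact exactly at 10 GPa."""
    assert soft_contact_bound() == pytest.approx(25e6 / 0.75, rel=1e-12)
    rods = RodPopulation()
    e_stiff = calibrated_stiff_bound(rods)
    heavy = 5606.0 * math.pi * ((76e-9 + 4 * 21e-9) / 2) ** 2 * (312e-9 + 4 * 171e-9)
    assert hertz_impact(heavy, 1.8, 1e-9, e_stiff).pressure_peak == pytest.approx(10e9, rel=1e-9)
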