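import math

import numpy as np
import pytest

from leaftemp import energy_balance as eb
from leaftemp.constants import (BoundaryLayerParams, PhysicalConstants,
                                RadiationConfig, TetensConstants)
from leaftemp.stomata import gs_to_velocity


def independent_delta_t(par, t_a, h, u, w, gs_mmol, p_atm=90.0):
    """Transcription of the two-term temperature quotient, coded separately
    from the package internals, used as the cross-check oracle."""
    a, b, c = 0.611, 17.502, 240.97
    esat = a * math.exp(b * t_a / (t_a + c))               # kPa
    d_pa = esat * (1 - h) * 1000.0
    s = 1000.0 * esat * b * c / (t_a + c) ** 2             # Pa/K
    rho = p_atm * 1000.0 / (287.05 * (t_a + 273.15))
    cpa = 1012.0
    gam = cpa * p_atm * 1000.0 / (0.622 * 2.45e6)
    g_bh = 0.0105 * (u / w) ** 0.5
    g_br = 4 * 0.97 * 5.670374419e-8 * (t_a + 273.15) ** 3 / (rho * cpa)
    r_bhr = 1.0 / (g_bh + g_br)
    r_bw = 1.0 / (1.08 * g_bh)
    r_lw = 1.0 / (gs_mmol / 1000.0 * 8.31446 * (t_a + 273.15) / (p_atm * 1000.0))
    rni = 0.50 * (par / 4.57) / 0.50
    denom = gam * (r_bw + r_lw) + s * r_bhr
    return (r_bhr * (r_bw + r_lw) * gam * rni / (rho * cpa * denom)
            - r_bhr * d_pa / denom)


class TestBoundaryLayerConductance:
    def test_unit_ratio_returns_coefficient(self):
        assert eb.boundary_layer_conductance_heat(0.1, 0.1) == 0.0105

    def test_square_root_wind_scaling(self):
        g1 = eb.boundary_layer_conductance_heat(1.0, 0.1)
        g4 = eb.boundary_layer_conductance_heat(4.0, 0.1)
        assert g4 == pytest.approx(2 * g1)

    def test_hand_value(self):
        assert eb.boundary_layer_conductance_heat(1.0, 0.1) == pytest.approx(
            0.0105 * math.sqrt(10.0), rel=1e-12)

    def test_wind_floor_bounds_resistance(self):
        assert (eb.boundary_layer_conductance_heat(0.0, 0.1)
                == eb.boundary_layer_conductance_heat(0.05, 0.1))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            eb.boundary_layer_conductance_heat(1.0, 0.0)


class TestRadiativeConductance:
    def test_hand_value_at_20C(self):
        assert eb.radiative_conductance(20.0) == pytest.approx(
            0.00512079730426036, rel=1e-9)

    def test_increases_with_temperature(self):
        assert eb.radiative_conductance(30.0) > eb.radiative_conductance(10.0)

    def test_zero_emissivity_gives_zero(self):
        k = PhysicalConstants(eps_leaf=0.0)
        assert eb.radiative_conductance(20.0, k) == 0.0


class TestPsychrometricConstant:
    def test_sea_level_value(self):
        k = PhysicalConstants(P_atm=101.325)
        assert eb.psychrometric_constant(k) == pytest.approx(67.288, abs=0.01)

    def test_linear_in_pressure(self):
        g1 = eb.psychrometric_constant(PhysicalConstants(P_atm=50.0))
        g2 = eb.psychrometric_constant(PhysicalConstants(P_atm=100.0))
        assert g2 == pytest.approx(2 * g1)

    def test_inverse_in_latent_heat(self):
        g1 = eb.psychrometric_constant(PhysicalConstants(lambda_v=2.45e6))
        g2 = eb.psychrometric_constant(PhysicalConstants(lambda_v=1.225e6))
        assert g2 == pytest.approx(2 * g1)


class TestNetIsothermalRadiation:
    def test_zero_par_equal_emissivities_gives_zero(self):
        assert eb.net_isothermal_radiation(0.0, 20.0) == 0.0

    def test_strictly_increasing_in_par(self):
        par = np.linspace(0, 2000, 30)
        rni = eb.net_isothermal_radiation(par, 20.0)
        assert np.all(np.diff(rni) > 0)

    def test_hand_value_at_1000(self):
        assert eb.net_isothermal_radiation(1000.0, 20.0) == pytest.approx(
            218.8183807439825, rel=1e-12)


class TestForwardModel:
    def test_zero_forcing_gives_zero_difference(self):
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        res = eb.leaf_air_temperature_difference(0.0, 20.0, 1.0, 1.0, 0.1, gs)
        assert res.delta_T_e == 0.0

    def test_sign_structure(self):
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        warm = eb.leaf_air_temperature_difference(1000.0, 20.0, 1.0, 1.0, 0.1, gs)
        cool = eb.leaf_air_temperature_difference(0.0, 20.0, 0.5, 1.0, 0.1, gs)
        assert warm.delta_T_e > 0 and cool.delta_T_e < 0

    def test_worked_case_matches_independent_oracle(self):
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        res = eb.leaf_air_temperature_difference(1500.0, 20.0, 0.7, 1.0, 0.1, gs)
        oracle = independent_delta_t(1500.0, 20.0, 0.7, 1.0, 0.1, 300.0)
        assert res.delta_T_e == pytest.approx(oracle, rel=1e-12)
        # frozen value of the oracle
        assert res.delta_T_e == pytest.approx(4.149472747260162, rel=1e-12)
        assert res.delta_T_e == pytest.approx(
            res.radiative_term - res.evaporative_term)
        assert res.T_Le == pytest.approx(20.0 + res.delta_T_e)

    def test_monotone_in_radiation_and_conductance(self):
        par = np.linspace(0, 2000, 20)
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        dte = eb.leaf_air_temperature_difference(par, 20.0, 0.7, 1.0, 0.1, gs).delta_T_e
        assert np.all(np.diff(dte) > 0)
        gs_grid = gs_to_velocity(np.linspace(50, 800, 20), 20.0, 90.0)
        dte2 = eb.leaf_air_temperature_difference(
            1500.0, 20.0, 0.7, 1.0, 0.1, gs_grid).delta_T_e
        assert np.all(np.diff(dte2) < 0)

    def test_well_coupled_limit(self):
        # vanishing boundary-layer resistance pins the leaf to air temperature
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        res = eb.leaf_air_temperature_difference(1500.0, 20.0, 0.7, 1e4, 0.01, gs)
        assert abs(res.delta_T_e) < 0.05

    def test_energy_closure(self):
        """Sensible + latent flux reconstructed from the returned state
        balances R_ni (the linearised budget is an algebraic identity)."""
        rng = np.random.default_rng(3)
        par = rng.uniform(0, 2000, 200)
        ta = rng.uniform(5, 35, 200)
        h = rng.uniform(0.3, 0.99, 200)
        u = rng.uniform(0.1, 4, 200)
        gs = gs_to_velocity(rng.uniform(50, 600, 200), ta, 90.0)
        res = eb.leaf_air_temperature_difference(par, ta, h, u, 0.08, gs)
        k = PhysicalConstants()
        rho = k.air_density(ta)
        rs = res.resistances
        sensible = rho * k.c_pa * res.delta_T_e / rs.r_b_HR
        d_pa = 1000.0 * (np.asarray(
            eb.saturation_vapour_pressure(ta)) * (1 - h))
        latent = (rho * k.c_pa / rs.gamma
                  * (rs.s * res.delta_T_e + d_pa) / (rs.r_b_W + rs.r_l_W))
        small = np.abs(res.delta_T_e) < 5.0
        np.testing.assert_allclose((sensible + latent)[small],
                                   res.R_ni[small], rtol=0.02, atol=1e-8)

    def test_nonpositive_stomatal_conductance_rejected(self):
        with pytest.raises(ValueError):
            eb.leaf_air_temperature_difference(1000.0, 20.0, 0.7, 1.0, 0.1, 0.0)


class TestInversion:
    def test_round_trip_single_state(self):
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        fwd = eb.leaf_air_temperature_difference(1500.0, 20.0, 0.7, 1.0, 0.1, gs)
        rbw, flag = eb.invert_boundary_resistance(
            float(fwd.delta_T_e), 1500.0, 20.0, 0.7, gs)
        assert flag == "ok"
        assert rbw == pytest.approx(float(fwd.resistances.r_b_W), rel=1e-6)

    def test_round_trip_grid(self, rng):
        n = 100
        par = rng.uniform(50, 2000, n)
        ta = rng.uniform(5, 35, n)
        h = rng.uniform(0.2, 0.99, n)
        u = rng.uniform(0.05, 5, n)
        w = rng.uniform(0.02, 0.25, n)
        gs = gs_to_velocity(rng.uniform(20, 800, n), ta, 90.0)
        fwd = eb.leaf_air_temperature_difference(par, ta, h, u, w, gs)
        rbw, flags = eb.invert_boundary_resistance(fwd.delta_T_e, par, ta, h,
                                                   gs, u=u, w=w)
        assert set(flags) <= {"ok", "multi_root"}
        np.testing.assert_allclose(rbw, fwd.resistances.r_b_W, rtol=1e-6)

    def test_degenerate_record_flagged(self):
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        rbw, flag = eb.invert_boundary_resistance(0.0, 0.0, 20.0, 1.0, gs)
        assert flag == "degenerate" and np.isnan(rbw)

    def test_unreachable_observation_flagged_invalid(self):
        # positive delta_T with zero radiation and positive D has no root
        gs = gs_to_velocity(300.0, 20.0, 90.0)
        rbw, flag = eb.invert_boundary_resistance(5.0, 0.0, 20.0, 0.5, gs)
        assert flag == "no_root" and np.isnan(rbw)
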