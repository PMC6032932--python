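"""Steady-state leaf energy balance and its inversion.

The forward model predicts the leaf-to-air temperature difference
(``delta_T_e``, degC) of a leaf from its microclimate (PAR, air
temperature, humidity, wind), its width and its stomatal conductance,
under a linearised steady-state balance with no heat storage:

    delta_T_e = r_bHR * (r_bW + r_lW) * gamma * R_ni
                / (rho_a * c_pa * [gamma * (r_bW + r_lW) + s * r_bHR])
              - r_bHR * D / [gamma * (r_bW + r_lW) + s * r_bHR]

The first (radiative) term warms the leaf in proportion to absorbed net
radiation; the second (evaporative) term cools it in proportion to the
vapour pressure deficit D (in Pa inside the equation).  Resistances are in
s/m: r_bHR is the parallel boundary-layer path for heat and thermal
radiation, r_bW and r_lW the boundary-layer and stomatal resistances to
water vapour.

The inversion recovers the boundary-layer resistance to water r_bW from
an *observed* temperature difference, holding the closure r_bW <-> r_bHR
coupling fixed; those inverted resistances feed the calibration module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (BoundaryLayerParams, PhysicalConstants,
                        RadiationConfig, TetensConstants, T_KELVIN)
from .microclimate import (saturation_vapour_pressure, svp_slope,
                           vapour_pressure_deficit)

__all__ = [
    "ResistanceSet",
    "EnergyBalanceResult",
    "boundary_layer_conductance_heat",
    "radiative_conductance",
    "psychrometric_constant",
    "net_isothermal_radiation",
    "resistance_network",
    "leaf_air_temperature_difference",
    "invert_boundary_resistance",
]


@dataclass
class ResistanceSet:
    """Conductances (m/s) and resistances (s/m) of one energy-balance state."""

    g_b_H: np.ndarray   # boundary layer, heat
    g_b_R: np.ndarray   # radiative "conductance"
    g_b_W: np.ndarray   # boundary layer, water vapour
    r_b_HR: np.ndarray  # 1 / (g_b_H + g_b_R)
    r_b_W: np.ndarray   # 1 / g_b_W
    r_l_W: np.ndarray   # 1 / g_s  (stomatal)
    gamma: float        # psychrometric constant, Pa/K
    s: np.ndarray       # saturation-curve slope at T_A, Pa/K


@dataclass
class EnergyBalanceResult:
    """Forward-model output: temperature terms plus the state that made them."""

    delta_T_e: np.ndarray      # degC, radiative_term - evaporative_term
    T_Le: np.ndarray           # degC, T_A + delta_T_e
    R_ni: np.ndarray           # W m-2
    radiative_term: np.ndarray
    evaporative_term: np.ndarray
    resistances: ResistanceSet


def boundary_layer_conductance_heat(u, w, p: BoundaryLayerParams = BoundaryLayerParams()):
    """Boundary-layer conductance to heat, g_b,H = a * (U/W)**b (m/s).

    Wind is floored at ``p.u_min`` so resistances stay bounded in still air.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("leaf width must be strictly positive")
    u_eff = np.maximum(np.asarray(u, dtype=float), p.u_min)
    out = p.a * (u_eff / w) ** p.b
    return out if out.ndim else float(out)


def radiative_conductance(t_a, k: PhysicalConstants = PhysicalConstants()):
    """Linearised radiative conductance g_b,R = 4 eps sigma T^3 / (rho c_p)."""
    t_a = np.asarray(t_a, dtype=float)
    if np.any(t_a <= -T_KELVIN):
        raise ValueError("air temperature below absolute zero")
    tk = t_a + T_KELVIN
    out = 4.0 * k.eps_leaf * k.sigma * tk**3 / (k.air_density(t_a) * k.c_pa)
    return out if out.ndim else float(out)


def psychrometric_constant(k: PhysicalConstants = PhysicalConstants()) -> float:
    """Psychrometric constant gamma = c_pa * P / (0.622 * lambda_v), Pa/K."""
    return k.c_pa * k.P_atm * 1000.0 / (0.622 * k.lambda_v)


def net_isothermal_radiation(par, t_a,
                             k: PhysicalConstants = PhysicalConstants(),
                             rcfg: RadiationConfig = RadiationConfig()):
    """Net isothermal radiation R_ni (W m-2) from PAR and air temperature.

    Shortwave: PAR (umol m-2 s-1) -> global shortwave energy via the quantum
    conversion and PAR fraction, scaled by leaf absorptance.  Longwave:
    isothermal exchange with a sky at air temperature; with equal sky and
    leaf emissivities (the default) it is exactly zero.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be non-negative")
    t_a = np.asarray(t_a, dtype=float)
    sw = rcfg.alpha_sw * (par / rcfg.q_conv) / rcfg.f_par
    lw = (k.eps_sky - k.eps_leaf) * k.sigma * (t_a + T_KELVIN) ** 4
    out = sw + lw
    return out if out.ndim else float(out)


def resistance_network(u, w, g_s_ms, t_a,
                       k: PhysicalConstants = PhysicalConstants(),
                       p: BoundaryLayerParams = BoundaryLayerParams(),
                       tet: TetensConstants = TetensConstants()) -> ResistanceSet:
    """Assemble the full conductance/resistance set for given conditions."""
    g_s_ms = np.asarray(g_s_ms, dtype=float)
    if np.any(g_s_ms <= 0):
        raise ValueError("stomatal conductance must be strictly positive")
    g_b_H = np.asarray(boundary_layer_conductance_heat(u, w, p))
    g_b_R = np.asarray(radiative_conductance(t_a, k))
    g_b_W = p.water_ratio * g_b_H
    return ResistanceSet(
        g_b_H=g_b_H, g_b_R=g_b_R, g_b_W=g_b_W,
        r_b_HR=1.0 / (g_b_H + g_b_R),
        r_b_W=1.0 / g_b_W,
        r_l_W=1.0 / g_s_ms,
        gamma=psychrometric_constant(k),
        s=np.asarray(svp_slope(t_a, tet)),
    )


def _delta_t_from_resistances(r_b_HR, r_b_W, r_l_W, gamma, s, rho_a, R_ni, D_pa, c_pa):
    """The two-term quotient: returns (radiative_term, evaporative_term)."""
    r_w = r_b_W + r_l_W
    denom = gamma * r_w + s * r_b_HR
    rad = r_b_HR * r_w * gamma * np.asarray(R_ni) / (rho_a * c_pa * denom)
    evap = r_b_HR * np.asarray(D_pa) / denom
    return rad, evap


def leaf_air_temperature_difference(
        par, t_a, h, u, w, g_s_ms,
        k: PhysicalConstants = PhysicalConstants(),
        p: BoundaryLayerParams = BoundaryLayerParams(),
        rcfg: RadiationConfig = RadiationConfig(),
        tet: TetensConstants = TetensConstants()) -> EnergyBalanceResult:
    """Forward energy balance: predict delta_T_e for one or many states.

    Parameters
    ----------
    par, t_a, h, u : scalar or array
        Microclimate at the leaf: PAR (umol m-2 s-1), air temperature
        (degC), relative humidity (proportion) and wind speed (m/s).
    w : scalar or array
        Leaf width, m.
    g_s_ms : scalar or array
        Stomatal conductance in velocity units (m/s); see
        :func:`leaftemp.stomata.gs_to_velocity`.
    """
    rs = resistance_network(u, w, g_s_ms, t_a, k, p, tet)
    R_ni = net_isothermal_radiation(par, t_a, k, rcfg)
    D_pa = 1000.0 * np.asarray(vapour_pressure_deficit(t_a, h, tet))
    rho_a = k.air_density(np.asarray(t_a, dtype=float))
    rad, evap = _delta_t_from_resistances(
        rs.r_b_HR, rs.r_b_W, rs.r_l_W, rs.gamma, rs.s, rho_a, R_ni, D_pa, k.c_pa)
    dte = rad - evap
    return EnergyBalanceResult(
        delta_T_e=dte, T_Le=np.asarray(t_a, dtype=float) + dte,
        R_ni=np.asarray(R_ni), radiative_term=np.asarray(rad),
        evaporative_term=np.asarray(evap), resistances=rs)


# ---------------------------------------------------------------------------
# inversion


def _delta_t_given_rbw(x, g_b_R, r_l_W, gamma, s, rho_a, R_ni, D_pa, c_pa,
                       water_ratio):
    """delta_T_e as a function of the unknown r_bW, holding the closure.

    The closure couples r_bHR to r_bW through the common heat conductance:
    g_b_H = 1 / (water_ratio * r_bW), r_bHR = 1 / (g_b_H + g_b_R).
    """
    g_b_H = 1.0 / (water_ratio * x)
    r_b_HR = 1.0 / (g_b_H + g_b_R)
    rad, evap = _delta_t_from_resistances(
        r_b_HR, x, r_l_W, gamma, s, rho_a, R_ni, D_pa, c_pa)
    return rad - evap


def invert_boundary_resistance(
        delta_T_obs, par, t_a, h, g_s_ms, u=None, w=None,
        k: PhysicalConstants = PhysicalConstants(),
        p: BoundaryLayerParams = BoundaryLayerParams(),
        rcfg: RadiationConfig = RadiationConfig(),
        tet: TetensConstants = TetensConstants()):
    """Solve the energy balance for r_bW given an observed delta_T.

    Returns ``(r_b_W, flags)`` arrays.  Flags: ``"ok"`` (unique positive
    root), ``"degenerate"`` (zero forcing, any resistance fits),
    ``"no_root"`` (no positive solution; excluded downstream),
    ``"multi_root"``.

    Holding the r_bHR <-> r_bW coupling, the balance is exactly quadratic
    in r_bW, so the solution is closed-form.  The inverse map is
    two-valued in part of the state space (an observation can sit on
    either side of the resistance at which the temperature response
    peaks), so a second positive root can exist.  When the wind speed
    ``u`` and leaf width ``w`` are supplied, the ambiguity is resolved
    physically: the root nearer (in log ratio) the forced-convection
    resistance implied by ``p`` at (u, w) is returned.  Without them the
    larger, boundary-layer-limited root is returned.  Either way the
    record is flagged ``multi_root``.

    Substituting the returned resistance back into the forward quotient,
    with the same r_bHR coupling, reproduces the observation to rounding
    error.
    """
    scalar_input = np.ndim(delta_T_obs) == 0
    delta_T_obs = np.atleast_1d(np.asarray(delta_T_obs, dtype=float))
    par = np.broadcast_to(np.asarray(par, dtype=float), delta_T_obs.shape)
    t_a = np.broadcast_to(np.asarray(t_a, dtype=float), delta_T_obs.shape)
    h = np.broadcast_to(np.asarray(h, dtype=float), delta_T_obs.shape)
    g_s = np.broadcast_to(np.asarray(g_s_ms, dtype=float), delta_T_obs.shape)

    gamma = psychrometric_constant(k)
    R_ni = np.broadcast_to(np.asarray(net_isothermal_radiation(par, t_a, k, rcfg)),
                           delta_T_obs.shape)
    D_pa = 1000.0 * np.broadcast_to(
        np.asarray(vapour_pressure_deficit(t_a, h, tet)), delta_T_obs.shape)
    s = np.broadcast_to(np.asarray(svp_slope(t_a, tet)), delta_T_obs.shape)
    g_b_R = np.broadcast_to(np.asarray(radiative_conductance(t_a, k)),
                            delta_T_obs.shape)
    rho_a = np.broadcast_to(np.asarray(k.air_density(t_a)), delta_T_obs.shape)

    prior = None
    if u is not None and w is not None:
        prior = np.broadcast_to(
            1.0 / (p.water_ratio
                   * np.asarray(boundary_layer_conductance_heat(u, w, p))),
            delta_T_obs.shape)

    out = np.full(delta_T_obs.shape, np.nan)
    flags = np.full(delta_T_obs.shape, "no_root", dtype=object)

    wr = p.water_ratio
    for i in np.ndindex(delta_T_obs.shape):
        if R_ni[i] == 0.0 and D_pa[i] == 0.0:
            flags[i] = "degenerate" if delta_T_obs[i] == 0.0 else "no_root"
            continue
        dt = delta_T_obs[i]
        r_l = 1.0 / g_s[i]
        q = gamma * R_ni[i] / (rho_a[i] * k.c_pa)
        # quadratic A x^2 + B x + C = 0 in x = r_bW, from clearing the
        # (1 + wr * g_bR * x) denominator of r_bHR
        A = wr * (dt * gamma * g_b_R[i] - q)
        B = (dt * gamma * (1.0 + wr * g_b_R[i] * r_l) + dt * s[i] * wr
             - q * wr * r_l + wr * D_pa[i])
        C = dt * gamma * r_l
        if A == 0.0:
            roots = [-C / B] if B != 0.0 else []
        else:
            disc = B * B - 4.0 * A * C
            if disc < 0.0:
                continue
            sq = np.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
        roots = sorted(r for r in roots if r > 0 and np.isfinite(r))
        if not roots:
            continue
        if len(roots) > 1 and prior is not None:
            out[i] = min(roots, key=lambda r: abs(np.log(r / prior[i])))
        else:
            out[i] = roots[-1]
        flags[i] = "multi_root" if len(roots) > 1 else "ok"

    if scalar_input:
        return float(out[0]), str(flags[0])
    return out, flags
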