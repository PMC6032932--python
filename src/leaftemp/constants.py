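"""Physical constants and configurable parameter blocks.

All parameter groups are frozen dataclasses so a configuration is hashable,
comparable and safe to share between pipeline stages.  Defaults follow the
standard biophysical literature (Campbell & Norman; Jones, *Plants and
Microclimate*) for a montane site at roughly 1,000 m elevation
(``P_atm`` = 90 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: Specific gas constant of dry air, J kg-1 K-1.
R_DRY_AIR = 287.05

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.31446

#: Stefan-Boltzmann constant, W m-2 K-4.
SIGMA_SB = 5.670374419e-8

#: Celsius -> Kelvin offset.
T_KELVIN = 273.15


@dataclass(frozen=True)
class TetensConstants:
    """Coefficients of the Tetens saturation-vapour-pressure curve.

    e_sat(T) = a * exp(b * T / (T + c)) with T in degrees Celsius and
    e_sat in kPa.
    """

    a: float = 0.611   # kPa
    b: float = 17.502  # dimensionless
    c: float = 240.97  # degC

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("Tetens constants must be strictly positive")


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants for the leaf energy balance.

    ``rho_a`` is the density of dry air; when ``None`` (default) it is
    computed from air temperature and ``P_atm`` by the ideal-gas law, a
    fixed value overrides that.  ``phi`` is the ratio of projected to total
    leaf area (0.5 for flat leaves).
    """

    rho_a: Optional[float] = None        # kg m-3; None -> ideal gas
    c_pa: float = 1012.0                 # J kg-1 K-1, dry air
    sigma: float = SIGMA_SB              # W m-2 K-4
    eps_sky: float = 0.97                # sky emissivity
    eps_leaf: float = 0.97               # leaf emissivity
    P_atm: float = 90.0                  # kPa (~1,000 m elevation)
    lambda_v: float = 2.45e6             # J kg-1, latent heat of vaporisation
    c_pw: float = 4181.0                 # J kg-1 K-1, liquid water
    c_pd: float = 2814.0                 # J kg-1 K-1, dry leaf matter
    phi: float = 0.5                     # projected / total leaf area

    def __post_init__(self) -> None:
        for name in ("c_pa", "sigma", "P_atm", "lambda_v", "c_pw", "c_pd", "phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("eps_sky", "eps_leaf"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rho_a is not None and self.rho_a <= 0:
            raise ValueError("rho_a override must be strictly positive")

    def air_density(self, t_a):
        """Density of dry air (kg m-3) at air temperature ``t_a`` (degC)."""
        if self.rho_a is not None:
            return self.rho_a
        return self.P_atm * 1000.0 / (R_DRY_AIR * (t_a + T_KELVIN))


@dataclass(frozen=True)
class BoundaryLayerParams:
    """Forced-convection boundary-layer conductance to heat.

    g_b,H = a * (U / W) ** b with wind speed U in m/s and leaf width W in m.
    The default coefficient 0.0105 m s^-1/2 with exponent 0.5 is the
    flat-plate engineering value; the calibration module re-estimates ``a``
    (and optionally ``b``) against inverted field resistances.
    """

    a: float = 0.0105  # m s^-1/2
    b: float = 0.5     # dimensionless exponent

    #: Diffusivity-ratio correction from heat to water vapour conductance.
    water_ratio: float = 1.08

    #: Wind floor (m/s) preventing unbounded resistances in still air.
    u_min: float = 0.05

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary-layer coefficient a must be > 0")
        if not (0 < self.b <= 1):
            raise ValueError("boundary-layer exponent b must lie in (0, 1]")


@dataclass(frozen=True)
class RadiationConfig:
    """Shortwave closure converting PAR to net isothermal radiation.

    R_ni = alpha_sw * (PAR / q_conv) / f_par
           + (eps_sky - eps_leaf) * sigma * (T_A + 273.15)**4

    with ``q_conv`` the quantum-to-energy conversion (umol per J) and
    ``f_par`` the PAR fraction of global shortwave.  With the default equal
    emissivities the longwave term vanishes exactly (sky temperature is
    taken equal to air temperature).
    """

    alpha_sw: float = 0.50  # shortwave absorptance
    q_conv: float = 4.57    # umol J-1
    f_par: float = 0.50     # PAR fraction of shortwave

    def __post_init__(self) -> None:
        if not (0 < self.alpha_sw <= 1):
            raise ValueError("alpha_sw must lie in (0, 1]")
        if self.q_conv <= 0 or not (0 < self.f_par <= 1):
            raise ValueError("q_conv must be > 0 and f_par in (0, 1]")


#: Floor on predicted stomatal conductance, mmol m-2 s-1.  Fitted linear
#: g_s(D) responses extrapolate below zero at large D, which is unphysical
#: and would put an infinite leaf resistance into the energy balance.
GS_FLOOR_MMOL = 5.0


def with_overrides(base, **kwargs):
    """Return a copy of a frozen parameter block with fields replaced."""
    return replace(base, **kwargs)
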