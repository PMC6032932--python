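"""Stomatal response to vapour pressure deficit, leaf traits, thermal inertia.

Spot porometer measurements of stomatal conductance g_s (mmol m-2 s-1)
decline roughly linearly with vapour pressure deficit D (kPa).  The
response is modelled as a linear mixed model with a species-specific slope
and intercept (D x species interaction in the fixed effects) and a random
intercept per leaf, so repeated measurements of the same leaf are not
treated as independent.  The fitted lines provide a continuous g_s time
series for each leaf from the microclimate D.

The module also carries the leaf trait table and the thermal time
constant tau (s), the e-folding time of leaf temperature after a step
change in the environment:

    tau = phi * LMA * [c_pw / LDMC + (c_pd - c_pw)] / H
    H   = rho_a * c_pa * (g_b,H + g_b,R + g_s * s / gamma)

with LMA in kg m-2 and H the total heat transfer coefficient
(W m-2 K-1) combining convection, radiation and transpiration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .constants import GS_FLOOR_MMOL, R_GAS, T_KELVIN, PhysicalConstants

__all__ = [
    "StomatalParams",
    "LeafTraits",
    "TauResult",
    "fit_gs_D_model",
    "predict_gs",
    "gs_to_velocity",
    "heat_transfer_coefficient",
    "thermal_time_constant",
    "read_traits_csv",
]


@dataclass
class StomatalParams:
    """Fitted g_s(D) line for one species with leaf-level intercept offsets."""

    species: str
    intercept: float                 # mmol m-2 s-1 at D = 0
    slope: float                     # mmol m-2 s-1 kPa-1
    intercept_se: float
    slope_se: float
    leaf_offsets: dict = field(default_factory=dict)  # leaf_id -> offset
    ols_fallback: bool = False


@dataclass
class LeafTraits:
    """Structural and positional traits of a single leaf."""

    leaf_id: str
    species: str
    width_m: float
    length_m: float
    area_m2: float
    thickness_mm: float
    lma_g_m2: float
    ldmc_g_g: float
    height_m: float
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.width_m, self.area_m2, self.lma_g_m2) <= 0:
            raise ValueError("width, area and LMA must be strictly positive")
        if not (0 < self.ldmc_g_g < 1):
            raise ValueError("LDMC must lie in (0, 1)")


@dataclass
class TauResult:
    tau: float  # s
    H: float    # W m-2 K-1


def fit_gs_D_model(spots: pd.DataFrame) -> dict[str, StomatalParams]:
    """Fit the g_s ~ D mixed model with leaf random intercepts.

    ``spots`` needs columns ``leaf_id``, ``species``, ``d_kpa``,
    ``gs_mmol_m2_s``.  Fixed effects are a separate intercept and D slope
    per species; the leaf random intercept is shared-variance across
    species.  Estimation is by REML.  When the random-effects structure is
    unidentifiable (fewer than two leaves in some species, or a singular
    fit) the model falls back to per-species ordinary least squares and
    flags the result.

    Returns a mapping species -> :class:`StomatalParams`.
    """
    required = {"leaf_id", "species", "d_kpa", "gs_mmol_m2_s"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spots table missing columns {sorted(missing)}")
    df = spots.dropna(subset=list(required)).copy()
    leaves_per_species = df.groupby("species")["leaf_id"].nunique()
    degenerate = bool((leaves_per_species < 2).any())

    if not degenerate:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    "gs_mmol_m2_s ~ 0 + C(species) + C(species):d_kpa",
                    df, groups=df["leaf_id"])
                fit = md.fit(reml=True)
            if np.isfinite(fit.cov_re.iloc[0, 0]) and fit.cov_re.iloc[0, 0] > 1e-8:
                return _params_from_mixed(fit, df)
            degenerate = True
        except Exception:
            degenerate = True

    warnings.warn("singular or unidentifiable mixed fit; "
                  "falling back to per-species OLS", stacklevel=2)
    return _params_from_ols(df)


def _params_from_mixed(fit, df) -> dict[str, StomatalParams]:
    out: dict[str, StomatalParams] = {}
    re = {leaf: float(v.iloc[0]) for leaf, v in fit.random_effects.items()}
    for sp, grp in df.groupby("species"):
        ikey = f"C(species)[{sp}]"
        skey = f"C(species)[{sp}]:d_kpa"
        offsets = {leaf: re[leaf] for leaf in grp["leaf_id"].unique()}
        out[sp] = StomatalParams(
            species=str(sp),
            intercept=float(fit.fe_params[ikey]),
            slope=float(fit.fe_params[skey]),
            intercept_se=float(fit.bse_fe[ikey]),
            slope_se=float(fit.bse_fe[skey]),
            leaf_offsets=offsets)
    return out


def _params_from_ols(df) -> dict[str, StomatalParams]:
    out: dict[str, StomatalParams] = {}
    for sp, grp in df.groupby("species"):
        fit = smf.ols("gs_mmol_m2_s ~ d_kpa", grp).fit()
        resid_by_leaf = (grp.assign(_r=fit.resid).groupby("leaf_id")["_r"]
                         .mean().to_dict())
        out[sp] = StomatalParams(
            species=str(sp),
            intercept=float(fit.params["Intercept"]),
            slope=float(fit.params["d_kpa"]),
            intercept_se=float(fit.bse["Intercept"]),
            slope_se=float(fit.bse["d_kpa"]),
            leaf_offsets={k: float(v) for k, v in resid_by_leaf.items()},
            ols_fallback=True)
    return out


def predict_gs(params: StomatalParams, leaf_id, d_kpa,
               g_min: float = GS_FLOOR_MMOL):
    """Predicted g_s (mmol m-2 s-1) for a leaf at vapour pressure deficit D.

    The species line is shifted by the leaf's random-intercept offset and
    floored at ``g_min`` so the prediction stays physically usable in the
    energy balance.
    """
    offset = params.leaf_offsets.get(leaf_id, 0.0)
    out = np.maximum(
        g_min,
        params.intercept + offset + params.slope * np.asarray(d_kpa, dtype=float))
    return out if np.ndim(out) else float(out)


def gs_to_velocity(gs_mmol, t_a, p_atm_kpa: float = 90.0):
    """Convert molar conductance (mmol m-2 s-1) to velocity units (m/s).

    g[m/s] = g[mol m-2 s-1] * R * T / P by the ideal-gas molar volume.
    """
    gs_mmol = np.asarray(gs_mmol, dtype=float)
    if np.any(gs_mmol <= 0):
        raise ValueError("stomatal conductance must be strictly positive")
    out = (gs_mmol / 1000.0) * R_GAS * (np.asarray(t_a, dtype=float) + T_KELVIN) \
        / (p_atm_kpa * 1000.0)
    return out if out.ndim else float(out)


def heat_transfer_coefficient(g_b_h, g_b_r, g_s_ms, s, gamma,
                              k: PhysicalConstants = PhysicalConstants(),
                              t_a=20.0):
    """Total heat transfer coefficient H (W m-2 K-1).

    H = rho_a * c_pa * (g_b,H + g_b,R + g_s * s / gamma): convective,
    radiative and transpirational paths in parallel, all in velocity units.
    """
    rho_a = k.air_density(np.asarray(t_a, dtype=float))
    out = rho_a * k.c_pa * (np.asarray(g_b_h, dtype=float)
                            + np.asarray(g_b_r, dtype=float)
                            + np.asarray(g_s_ms, dtype=float)
                            * np.asarray(s, dtype=float) / gamma)
    return out if np.ndim(out) else float(out)


def thermal_time_constant(traits: LeafTraits, H,
                          k: PhysicalConstants = PhysicalConstants()):
    """Thermal time constant tau (s) of a leaf.

    tau = phi * LMA * [c_pw / LDMC + (c_pd - c_pw)] / H, with LMA
    converted from g m-2 to kg m-2.  The bracket is the heat capacity per
    unit dry mass of the hydrated leaf: water held per unit dry matter
    (1/LDMC) at c_pw, plus the dry matter itself at c_pd.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("heat transfer coefficient must be strictly positive")
    lma_kg = traits.lma_g_m2 / 1000.0
    heat_capacity = k.c_pw / traits.ldmc_g_g + (k.c_pd - k.c_pw)
    tau = k.phi * lma_kg * heat_capacity / H
    if np.ndim(tau):
        return [TauResult(tau=float(t), H=float(hh)) for t, hh in zip(tau, H)]
    return TauResult(tau=float(tau), H=float(H))


def read_traits_csv(path) -> dict[str, LeafTraits]:
    """Read the per-leaf trait table (one row per leaf) keyed by leaf_id."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        t = LeafTraits(
            leaf_id=str(row["leaf_id"]), species=str(row["species"]),
            width_m=float(row["width_m"]), length_m=float(row["length_m"]),
            area_m2=float(row["area_m2"]),
            thickness_mm=float(row["thickness_mm"]),
            lma_g_m2=float(row["lma_g_m2"]), ldmc_g_g=float(row["ldmc_g_g"]),
            height_m=float(row["height_m"]),
            angle_deg=float(row.get("angle_deg", 0.0)))
        out[t.leaf_id] = t
    return out
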