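"""Counterfactual trait substitution: which trait drives the species gap?

A base leaf's temperature series is re-predicted with components of a
donor species' parameterisation substituted singly and in combination:
leaf width (boundary-layer geometry), the g_s-D intercept (baseline
stomatal aperture) and the g_s-D slope (stomatal sensitivity to dryness).
The base leaf keeps its own microclimate stream — height and exposure are
part of the leaf, not of the swapped traits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import (BoundaryLayerParams, PhysicalConstants,
                        RadiationConfig, GS_FLOOR_MMOL)
from .energy_balance import leaf_air_temperature_difference
from .microclimate import vapour_pressure_deficit
from .stomata import LeafTraits, StomatalParams, gs_to_velocity, predict_gs

__all__ = ["SwapSpec", "run_trait_swap", "VALID_COMPONENTS"]

VALID_COMPONENTS = ("width", "gs_intercept", "gs_slope")


@dataclass(frozen=True)
class SwapSpec:
    base_leaf: str
    donor_species: str
    components: tuple
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("components must be non-empty")
        bad = set(self.components) - set(VALID_COMPONENTS)
        if bad:
            raise ValueError(f"unknown swap components: {sorted(bad)}")


def _apply_components(components: Iterable[str], width: float,
                      gs: StomatalParams, donor_width: float,
                      donor_gs: StomatalParams):
    comps = set(components)
    if "width" in comps:
        width = donor_width
    if "gs_intercept" in comps:
        gs = replace(gs, intercept=donor_gs.intercept)
    if "gs_slope" in comps:
        gs = replace(gs, slope=donor_gs.slope)
    return width, gs


def run_trait_swap(base_traits: LeafTraits, base_gs: StomatalParams,
                   donor_width: float, donor_gs: StomatalParams,
                   microclimate: pd.DataFrame,
                   variants: Iterable[Iterable[str]] = ((), ("width",),
                                                        ("gs_intercept",),
                                                        ("gs_slope",),
                                                        VALID_COMPONENTS),
                   k: PhysicalConstants = PhysicalConstants(),
                   p: BoundaryLayerParams = BoundaryLayerParams(),
                   rcfg: RadiationConfig = RadiationConfig(),
                   par_bin_width: float = 250.0):
    """Re-predict delta_T_e for the base leaf under each trait variant.

    ``microclimate`` is the base leaf's stream with columns ``par``,
    ``ta``, ``rh``, ``wind``.  ``variants`` is an iterable of component
    subsets; the empty subset is the base parameterisation and is always
    included first.  Returns ``(series, summary)``: a DataFrame of
    delta_T_e per variant, and mean delta_T_e per PAR bin per variant.
    """
    mc = microclimate
    d_kpa = np.asarray(vapour_pressure_deficit(
        mc["ta"].to_numpy(float), mc["rh"].to_numpy(float)))

    variant_list = [tuple(v) for v in variants]
    if () not in variant_list:
        variant_list.insert(0, ())

    series = pd.DataFrame({"time": mc["time"].to_numpy(),
                           "par": mc["par"].to_numpy(float)})
    for comps in variant_list:
        width, gs_params = _apply_components(
            comps, base_traits.width_m, base_gs, donor_width, donor_gs)
        gs_mmol = predict_gs(gs_params, base_traits.leaf_id, d_kpa,
                             g_min=GS_FLOOR_MMOL)
        gs_ms = gs_to_velocity(gs_mmol, mc["ta"].to_numpy(float), k.P_atm)
        res = leaf_air_temperature_difference(
            mc["par"].to_numpy(float), mc["ta"].to_numpy(float),
            mc["rh"].to_numpy(float), mc["wind"].to_numpy(float),
            width, gs_ms, k=k, p=p, rcfg=rcfg)
        label = "base" if not comps else "+".join(comps)
        series[label] = res.delta_T_e

    par_bin = np.floor(series["par"].to_numpy(float) / par_bin_width) * par_bin_width
    value_cols = [c for c in series.columns if c not in ("time", "par")]
    summary = (series.assign(par_bin=par_bin)
               .groupby("par_bin")[value_cols].mean().reset_index())
    return series, summary
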