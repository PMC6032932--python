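"""Seeded synthetic canopy data with the structure the analysis assumes.

The generators emulate a 10-day montane-forest campaign: a diurnal PAR
cycle with per-day brightness and multiplicative cloud flicker, Beer-law
vertical attenuation, a damped air-temperature profile, humidity linearly
(negatively) coupled to air temperature, low lognormal within-canopy wind,
species-specific linear g_s-D responses with leaf-level random intercepts,
and leaf temperature series produced by the forward energy balance plus
measurement noise and optional PAR-mismatch corruption of whole 20-minute
windows (the tower sensor disagreeing with the leaf surface).

Every generator is a pure function of (scenario, seed): the same scenario
yields byte-identical output.  Distinct sub-streams keep the leaf roster,
sky, spot sampling and corruption draws independent of one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (BoundaryLayerParams, GS_FLOOR_MMOL,
                        PhysicalConstants, RadiationConfig)
from .energy_balance import leaf_air_temperature_difference
from .microclimate import vapour_pressure_deficit
from .stomata import gs_to_velocity

__all__ = [
    "SpeciesSpec",
    "SyntheticScenario",
    "default_scenario",
    "gen_leaves",
    "gen_microclimate",
    "gen_stomatal_observations",
    "gen_leaf_temperature_series",
]

T0 = pd.Timestamp("2016-10-01 00:00:00")


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground-truth parameters of one synthetic species."""

    name: str
    gs_intercept: float          # mmol m-2 s-1 at D = 0
    gs_slope: float              # mmol m-2 s-1 kPa-1
    boundary_a: float            # m s^-1/2, one-parameter truth (b = 0.5)
    width_m: float
    lma_g_m2: float
    ldmc_g_g: float
    n_leaves: int
    height_range: tuple          # (lo, hi) m
    gs_leaf_sd: float = 30.0     # SD of leaf intercept offsets
    gs_residual_sd: float = 40.0 # spot residual SD


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int = 0
    n_days: int = 10
    cadence_s: int = 10
    heights: tuple = (2.0, 8.0, 12.5, 18.0, 25.0)
    species: tuple = ()
    par_max: float = 2000.0          # clear-sky top-of-canopy peak
    lai_total: float = 4.0           # cumulative leaf area index to ground
    k_ext: float = 0.5               # Beer-law extinction coefficient
    ta_night: float = 12.4           # degC
    ta_amplitude: float = 10.0       # degC, clear-day amplitude at canopy top
    rh_intercept: float = 1.25       # proportion (at T_A = 0)
    rh_slope: float = -0.03          # proportion per degC
    rh_noise_sd: float = 0.03
    u_above: float = 1.0             # m/s mean at canopy top
    u_within: float = 0.26           # m/s mean within canopy
    u_sigma: float = 0.5             # lognormal shape
    cloud_flicker_prob: float = 0.3
    cloud_flicker_depth: float = 0.6
    dt_noise_sd: float = 0.05        # degC thermocouple noise
    par_corruption_rate: float = 0.2 # fraction of daytime 20-min windows
    corruption_factors: tuple = (0.3, 2.0)
    rh_missing_frac: float = 0.0     # leading fraction of days without rh

    def __post_init__(self) -> None:
        for name in ("cloud_flicker_prob", "par_corruption_rate",
                     "rh_missing_frac"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dt_noise_sd < 0 or self.rh_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def default_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """The shipped three-species scenario.

    Stomatal truths are the overstorey/subcanopy parameter sets the
    package's contrast analyses target (high-intercept steep-slope
    overstorey species B, shallower species A, low-conductance
    understorey species C); boundary-layer coefficient truths for the two
    overstorey species are the one-parameter calibration values.
    """
    species = (
        SpeciesSpec("alchornea", 325.1, -68.8, 0.0171, width_m=0.06,
                    lma_g_m2=90.0, ldmc_g_g=0.37, n_leaves=10,
                    height_range=(8.0, 18.0)),
        SpeciesSpec("miconia", 401.6, -189.8, 0.0215, width_m=0.12,
                    lma_g_m2=140.0, ldmc_g_g=0.42, n_leaves=9,
                    height_range=(8.0, 14.0)),
        SpeciesSpec("guapira", 185.4, -212.7, 0.0105, width_m=0.035,
                    lma_g_m2=85.0, ldmc_g_g=0.20, n_leaves=4,
                    height_range=(1.5, 4.0)),
    )
    return SyntheticScenario(seed=seed, species=species, **overrides)


def _rng(scn: SyntheticScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(scn.seed), stream])


def gen_leaves(scn: SyntheticScenario) -> pd.DataFrame:
    """The leaf roster shared by all generators: traits plus g_s offsets."""
    rng = _rng(scn, 1)
    rows = []
    for sp in scn.species:
        hts = np.linspace(*sp.height_range, sp.n_leaves)
        widths = sp.width_m * rng.uniform(0.9, 1.1, sp.n_leaves)
        offsets = rng.normal(0.0, sp.gs_leaf_sd, sp.n_leaves)
        for i in range(sp.n_leaves):
            rows.append({
                "leaf_id": f"{sp.name[0].upper()}{i + 1}",
                "species": sp.name,
                "width_m": float(widths[i]),
                "length_m": float(widths[i] * 2.0),
                "area_m2": float(widths[i] ** 2 * 1.4),
                "thickness_mm": 0.3,
                "lma_g_m2": sp.lma_g_m2,
                "ldmc_g_g": sp.ldmc_g_g,
                "height_m": float(hts[i]),
                "angle_deg": float(rng.uniform(0, 30)),
                "gs_offset": float(offsets[i]),
            })
    return pd.DataFrame(rows)


def _sky(scn: SyntheticScenario):
    """Shared sky state: times (s), solar shape, per-record PAR at canopy top."""
    rng = _rng(scn, 2)
    t = np.arange(0, scn.n_days * 86400, scn.cadence_s, dtype=np.int64)
    tod = (t % 86400) / 3600.0
    solar = np.sin(np.pi * (tod - 6.0) / 12.0)
    solar[solar < 1e-9] = 0.0  # exact night, incl. the dusk rounding sliver
    day = (t // 86400).astype(int)
    brightness = rng.uniform(0.35, 1.0, scn.n_days)
    block = t // 600  # 10-min flicker blocks
    n_blocks = int(block[-1]) + 1
    flicker = np.ones(n_blocks)
    hit = rng.random(n_blocks) < scn.cloud_flicker_prob
    flicker[hit] = 1.0 - scn.cloud_flicker_depth * rng.random(hit.sum())
    par_top = scn.par_max * solar * brightness[day] * flicker[block]
    return t, tod, solar, day, brightness, par_top


def _profiles(scn: SyntheticScenario):
    """Deterministic per-height microclimate arrays (true, unmasked)."""
    t, tod, solar, day, brightness, par_top = _sky(scn)
    rng = _rng(scn, 3)
    z_top = max(scn.heights)
    frames = {}
    for z in scn.heights:
        lai_above = scn.lai_total * (z_top - z) / z_top
        par = par_top * np.exp(-scn.k_ext * lai_above)
        damp = 0.6 + 0.4 * z / z_top
        ta = (scn.ta_night
              + scn.ta_amplitude * brightness[day] * damp * solar**1.5
              + rng.normal(0.0, 0.1, len(t)))
        rh = np.clip(scn.rh_intercept + scn.rh_slope * ta
                     + rng.normal(0.0, scn.rh_noise_sd, len(t)), 0.3, 1.0)
        u_mean = (scn.u_within + (scn.u_above - scn.u_within)
                  * max(0.0, (z - 11.5) / (z_top - 11.5)))
        u = rng.lognormal(np.log(u_mean) - scn.u_sigma**2 / 2, scn.u_sigma,
                          len(t))
        frames[z] = {"par": par, "ta": ta, "rh": rh, "wind": u}
    return t, frames


def gen_microclimate(scn: SyntheticScenario) -> pd.DataFrame:
    """Wide per-record microclimate table over all sensor heights.

    Night records (zero solar elevation) have PAR exactly 0.  When
    ``rh_missing_frac`` > 0, humidity in the leading fraction of days is
    masked to emulate a late-starting sensor.
    """
    t, frames = _profiles(scn)
    times = T0 + pd.to_timedelta(t, unit="s")
    cut = scn.rh_missing_frac * scn.n_days * 86400
    parts = []
    for z in scn.heights:
        f = frames[z]
        rh = f["rh"].copy()
        rh[t < cut] = np.nan
        parts.append(pd.DataFrame({
            "time": times, "height_m": z, "par": f["par"], "ta": f["ta"],
            "rh": rh, "wind": f["wind"]}))
    return (pd.concat(parts, ignore_index=True)
            .sort_values(["time", "height_m"], kind="stable")
            .reset_index(drop=True))


def _nearest_height(scn: SyntheticScenario, z: float) -> float:
    return min(scn.heights, key=lambda h: abs(h - z))


def gen_stomatal_observations(scn: SyntheticScenario,
                              n_spots_per_leaf: int = 20) -> pd.DataFrame:
    """Porometer-style daytime spot measurements of g_s for every leaf.

    g_s = species intercept + leaf offset + species slope * D + residual,
    with D taken from the generated microclimate at the leaf's nearest
    sensor height.  No spots are generated at night.
    """
    t, frames = _profiles(scn)
    leaves = gen_leaves(scn)
    rng = _rng(scn, 4)
    tod = (t % 86400) / 3600.0
    day_idx = np.flatnonzero((tod >= 8.0) & (tod <= 17.0))
    spmap = {sp.name: sp for sp in scn.species}
    rows = []
    for _, leaf in leaves.iterrows():
        sp = spmap[leaf["species"]]
        zz = _nearest_height(scn, leaf["height_m"])
        pick = rng.choice(day_idx, size=n_spots_per_leaf, replace=False)
        d = np.asarray(vapour_pressure_deficit(
            frames[zz]["ta"][pick], frames[zz]["rh"][pick]))
        gs = (sp.gs_intercept + leaf["gs_offset"] + sp.gs_slope * d
              + rng.normal(0.0, sp.gs_residual_sd, n_spots_per_leaf))
        for j in range(n_spots_per_leaf):
            rows.append({"leaf_id": leaf["leaf_id"],
                         "species": leaf["species"],
                         "time": T0 + pd.Timedelta(int(t[pick[j]]), "s"),
                         "d_kpa": float(d[j]),
                         "gs_mmol_m2_s": float(gs[j]),
                         "par_leaf": float(frames[zz]["par"][pick[j]])})
    return pd.DataFrame(rows).sort_values(["leaf_id", "time"]).reset_index(drop=True)


def gen_leaf_temperature_series(
        scn: SyntheticScenario,
        k: PhysicalConstants = PhysicalConstants(),
        rcfg: RadiationConfig = RadiationConfig()) -> pd.DataFrame:
    """Observed delta_T streams plus the forward-model ground truth.

    For each leaf, the microclimate at its height drives the forward
    energy balance under the leaf's true traits, true g_s(D) line and its
    species' true boundary-layer coefficient.  The *observed* series adds
    Gaussian thermocouple noise; in a fraction ``par_corruption_rate`` of
    daytime 20-minute windows, the PAR used for the truth is rescaled by a
    factor drawn from ``corruption_factors`` while the recorded microclimate
    PAR is left unchanged (tower/leaf-surface mismatch).

    Returns a long DataFrame with per-record recorded microclimate, the
    true and observed delta_T, the corruption flag and the true g_s.
    """
    t, frames = _profiles(scn)
    leaves = gen_leaves(scn)
    rng = _rng(scn, 5)
    times = T0 + pd.to_timedelta(t, unit="s")
    tod = (t % 86400) / 3600.0
    z_top = max(scn.heights)
    par_top = frames[z_top]["par"]
    win = t // 1200
    n_win = int(win[-1]) + 1
    # a window is "daytime" if any of its records has top-of-canopy PAR > 5
    day_win = np.zeros(n_win, dtype=bool)
    np.maximum.at(day_win, win, par_top > 5.0)

    spmap = {sp.name: sp for sp in scn.species}
    out = []
    for _, leaf in leaves.iterrows():
        sp = spmap[leaf["species"]]
        zz = _nearest_height(scn, leaf["height_m"])
        f = frames[zz]
        hs = np.array(scn.heights)
        us = np.vstack([frames[z]["wind"] for z in scn.heights])
        zi = np.clip(np.searchsorted(hs, leaf["height_m"]), 1, len(hs) - 1)
        z_lo, z_hi = hs[zi - 1], hs[zi]
        frac = np.clip((leaf["height_m"] - z_lo) / (z_hi - z_lo), 0.0, 1.0)
        u = us[zi - 1] * (1 - frac) + us[zi] * frac

        # per-leaf window corruption draws
        corrupt = rng.random(n_win) < scn.par_corruption_rate
        corrupt &= day_win
        factors = rng.choice(np.asarray(scn.corruption_factors), size=n_win)
        par_true = f["par"] * np.where(corrupt[win], factors[win], 1.0)

        d = np.asarray(vapour_pressure_deficit(f["ta"], f["rh"]))
        gs_mmol = np.maximum(GS_FLOOR_MMOL,
                             sp.gs_intercept + leaf["gs_offset"]
                             + sp.gs_slope * d)
        gs_ms = gs_to_velocity(gs_mmol, f["ta"], k.P_atm)
        res = leaf_air_temperature_difference(
            par_true, f["ta"], f["rh"], u, leaf["width_m"], gs_ms,
            k=k, p=BoundaryLayerParams(a=sp.boundary_a), rcfg=rcfg)
        dt_true = res.delta_T_e
        dt_obs = dt_true + rng.normal(0.0, scn.dt_noise_sd, len(t))
        out.append(pd.DataFrame({
            "time": times, "leaf_id": leaf["leaf_id"],
            "species": leaf["species"], "height_m": leaf["height_m"],
            "par": f["par"], "ta": f["ta"], "rh": f["rh"], "wind": u,
            "d_kpa": d, "gs_true_mmol": gs_mmol,
            "dt_true": dt_true, "dt_obs": dt_obs,
            "window_corrupted": corrupt[win]}))
    return pd.concat(out, ignore_index=True)
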