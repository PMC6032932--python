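"""End-to-end pipeline: simulate -> derive -> fit -> predict -> invert ->
calibrate -> select windows -> contrast -> trait swap.

The configuration is a plain YAML-serialisable dataclass; all randomness
flows from a single top-level seed that is split into per-stage streams,
so the same configuration reproduces an identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, microclimate, stomata, synthetic, traitswap, windows
from .constants import BoundaryLayerParams, PhysicalConstants, RadiationConfig
from .energy_balance import invert_boundary_resistance, leaf_air_temperature_difference
from .stomata import gs_to_velocity, predict_gs

log = logging.getLogger("leaftemp")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "leaftemp_run"
    n_days: int = 10
    cadence_s: int = 10
    par_corruption_rate: float = 0.2
    rh_missing_frac: float = 0.3
    n_spots_per_leaf: int = 20
    # window gates
    slope_band: tuple = windows.SLOPE_BAND
    intercept_band: tuple = windows.INTERCEPT_BAND
    window_width_s: int = windows.WINDOW_WIDTH_S
    n_min: int = windows.N_MIN
    # inversion economics: cap on points inverted per species
    max_invert_points: int = 4000
    # contrast bin (high PAR and T_A for the default synthetic climate)
    contrast_bin: dict = field(default_factory=lambda: dict(
        label="high", par_lo=600.0, par_hi=1200.0, ta_lo=16.0, ta_hi=20.0,
        u_lo=0.05, u_hi=1.5))
    # physical overrides (kept flat for YAML round-tripping)
    p_atm_kpa: float = 90.0
    boundary_a: float = 0.0105
    boundary_b: float = 0.5


def save_config(cfg: PipelineConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["slope_band"] = list(d["slope_band"])
    d["intercept_band"] = list(d["intercept_band"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["slope_band"] = tuple(d["slope_band"])
    d["intercept_band"] = tuple(d["intercept_band"])
    return PipelineConfig(**d)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the summary dict.

    Writes stage CSVs, ``summary.json`` and ``run.log`` into
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = _time.time()
    summary: dict = {"config": dataclasses.asdict(cfg)}
    k = PhysicalConstants(P_atm=cfg.p_atm_kpa)
    p_default = BoundaryLayerParams(a=cfg.boundary_a, b=cfg.boundary_b)
    rcfg = RadiationConfig()

    try:
        # 1. simulate
        scn = synthetic.default_scenario(
            seed=cfg.seed, n_days=cfg.n_days, cadence_s=cfg.cadence_s,
            par_corruption_rate=cfg.par_corruption_rate,
            rh_missing_frac=cfg.rh_missing_frac)
        mc = synthetic.gen_microclimate(scn)
        spots = synthetic.gen_stomatal_observations(scn, cfg.n_spots_per_leaf)
        leaf_series = synthetic.gen_leaf_temperature_series(scn, k=k, rcfg=rcfg)
        leaves = synthetic.gen_leaves(scn)
        microclimate.write_microclimate_csv(
            microclimate.derive(mc), out / "microclimate.csv")
        spots.to_csv(out / "spots.csv", index=False)
        leaves.drop(columns=["gs_offset"]).to_csv(out / "traits.csv", index=False)
        log.info("simulate: %d microclimate records, %d spots, %d leaves",
                 len(mc), len(spots), len(leaves))

        # 2. derive: gap-fill humidity from the available tail, recompute D
        hum = microclimate.fit_humidity_model(mc)
        mc_filled = microclimate.gap_fill_humidity(mc, hum)
        summary["humidity_r2"] = hum.r_squared
        log.info("derive: humidity R2 by height %s", hum.r_squared)

        # 3. fit stomatal model
        gs_params = stomata.fit_gs_D_model(spots)
        truth = {sp.name: (sp.gs_intercept, sp.gs_slope) for sp in scn.species}
        summary["stomatal"] = {
            sp: {"intercept": prm.intercept, "intercept_se": prm.intercept_se,
                 "slope": prm.slope, "slope_se": prm.slope_se,
                 "true_intercept": truth[sp][0], "true_slope": truth[sp][1],
                 "ols_fallback": prm.ols_fallback}
            for sp, prm in gs_params.items()}
        log.info("stomata: %s", {s: (round(v.intercept, 1), round(v.slope, 1))
                                 for s, v in gs_params.items()})

        # 4. predict delta_T_e with default boundary constants
        ls = leaf_series
        gs_hat = np.empty(len(ls))
        for leaf_id, grp in ls.groupby("leaf_id"):
            sp = grp["species"].iloc[0]
            gs_hat[grp.index] = predict_gs(gs_params[sp], leaf_id,
                                           grp["d_kpa"].to_numpy())
        widths = leaves.set_index("leaf_id")["width_m"]
        w_arr = ls["leaf_id"].map(widths).to_numpy(float)
        gs_ms = gs_to_velocity(gs_hat, ls["ta"].to_numpy(), cfg.p_atm_kpa)
        pred0 = leaf_air_temperature_difference(
            ls["par"].to_numpy(), ls["ta"].to_numpy(), ls["rh"].to_numpy(),
            ls["wind"].to_numpy(), w_arr, gs_ms, k=k, p=p_default, rcfg=rcfg)
        ls = ls.assign(dt_est=pred0.delta_T_e, gs_hat_mmol=gs_hat,
                       gs_hat_ms=gs_ms, width_m=w_arr)

        # 5. invert r_bW on bright records (PAR >= 200), capped per species;
        # per-wind-bin outlier fences then screen the raw points before the
        # least-squares fit, which absorbs PAR-mismatch corruption
        rng = np.random.default_rng([cfg.seed, 10])
        calib = {}
        for sp_name in ("alchornea", "miconia"):
            sub = ls[(ls["species"] == sp_name) & (ls["par"] >= 200.0)]
            if len(sub) > cfg.max_invert_points:
                sub = sub.sample(cfg.max_invert_points, random_state=int(
                    rng.integers(0, 2**31 - 1)))
            r_bw, flags = invert_boundary_resistance(
                sub["dt_obs"].to_numpy(), sub["par"].to_numpy(),
                sub["ta"].to_numpy(), sub["rh"].to_numpy(),
                sub["gs_hat_ms"].to_numpy(), k=k, p=p_default, rcfg=rcfg)
            inv = sub.assign(r_b_w=r_bw, flag=flags, u=sub["wind"])
            inv[["time", "leaf_id", "u", "par", "r_b_w", "flag"]].to_csv(
                out / f"inverted_{sp_name}.csv", index=False)
            ok = (inv["flag"].isin(["ok", "multi_root"])).to_numpy()
            ok &= calibration.tukey_keep_mask(inv["u"].to_numpy(),
                                              inv["r_b_w"].to_numpy())
            # 6. calibrate
            fit = calibration.fit_boundary_constants(
                inv.loc[ok, "u"], inv.loc[ok, "width_m"],
                inv.loc[ok, "r_b_w"], model="one_param")
            true_a = {sp.name: sp.boundary_a for sp in scn.species}[sp_name]
            calib[sp_name] = {"a": fit.a, "a_se": fit.a_se, "true_a": true_a,
                              "n": fit.n_points}
            log.info("calibrate %s: a=%.5f (true %.5f, n=%d)",
                     sp_name, fit.a, true_a, fit.n_points)
        summary["boundary_calibration"] = calib

        # 7. re-predict with calibrated constants, select windows
        dt_est2 = np.empty(len(ls))
        for sp_name, grp in ls.groupby("species"):
            a_hat = calib.get(sp_name, {}).get("a", cfg.boundary_a)
            res = leaf_air_temperature_difference(
                grp["par"].to_numpy(), grp["ta"].to_numpy(),
                grp["rh"].to_numpy(), grp["wind"].to_numpy(),
                grp["width_m"].to_numpy(), grp["gs_hat_ms"].to_numpy(),
                k=k, p=BoundaryLayerParams(a=a_hat, b=cfg.boundary_b),
                rcfg=rcfg)
            dt_est2[grp.index] = res.delta_T_e
        ls = ls.assign(dt_est=dt_est2)
        par_top_by_time = ls.groupby("time")["par"].max()
        daytime = ls["time"].map(par_top_by_time) > windows.DAYTIME_PAR
        day_ls = ls[daytime]
        diags, mask = windows.select_windows(
            day_ls, width_s=cfg.window_width_s, n_min=cfg.n_min,
            slope_band=cfg.slope_band, intercept_band=cfg.intercept_band)
        n_sel = sum(d.selected for d in diags)
        eligible = [d for d in diags if "n_min" not in d.reason]
        summary["window_selection"] = {
            "n_windows": len(eligible), "n_selected": n_sel,
            "fraction": n_sel / max(len(eligible), 1)}
        pd.DataFrame([dataclasses.asdict(d) for d in diags]).to_csv(
            out / "window_diagnostics.csv", index=False)
        log.info("windows: %d/%d selected", n_sel, len(eligible))

        # 8. species contrast in the configured microclimate bin
        selected = day_ls[mask.to_numpy()]
        bin_ = windows.MicroclimateBin(**cfg.contrast_bin)
        sub = windows.subset_by_microclimate(
            selected[selected["species"].isin(["alchornea", "miconia"])], bin_)
        if (len(sub) and sub["species"].nunique() == 2
                and (sub.groupby("species")["leaf_id"].nunique() >= 2).all()):
            diff, se, pval, fit = windows.compare_species(sub)
            r2m, r2c = windows.pseudo_r_squared(fit) \
                if hasattr(fit, "fe_params") else (np.nan, np.nan)
            summary["species_contrast"] = {
                "bin": bin_.label, "n": len(sub), "difference": diff,
                "se": se, "p": pval, "r2_marginal": r2m, "r2_conditional": r2c}
        else:
            summary["species_contrast"] = {"bin": bin_.label, "n": len(sub),
                                           "note": "insufficient data in bin"}

        # 9. trait swap: first base-species leaf takes donor-species traits
        base_leaf = leaves[leaves["species"] == "alchornea"].iloc[-1]
        donor = [s for s in scn.species if s.name == "miconia"][0]
        base_traits = stomata.LeafTraits(
            leaf_id=base_leaf["leaf_id"], species="alchornea",
            width_m=base_leaf["width_m"], length_m=base_leaf["length_m"],
            area_m2=base_leaf["area_m2"], thickness_mm=base_leaf["thickness_mm"],
            lma_g_m2=base_leaf["lma_g_m2"], ldmc_g_g=base_leaf["ldmc_g_g"],
            height_m=base_leaf["height_m"])
        base_mc = ls[ls["leaf_id"] == base_leaf["leaf_id"]][
            ["time", "par", "ta", "rh", "wind"]]
        _, swap_summary = traitswap.run_trait_swap(
            base_traits, gs_params["alchornea"], donor.width_m,
            gs_params["miconia"], base_mc, k=k,
            p=BoundaryLayerParams(a=calib["alchornea"]["a"]), rcfg=rcfg)
        swap_summary.to_csv(out / "trait_swap.csv", index=False)
        summary["trait_swap_high_par"] = (
            swap_summary[swap_summary["par_bin"] >= 1000.0]
            .drop(columns="par_bin").mean().to_dict())

        summary["runtime_s"] = round(_time.time() - t0, 1)
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=float))
        log.info("pipeline complete in %.1f s", summary["runtime_s"])
        return summary
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
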