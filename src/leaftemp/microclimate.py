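"""Canopy microclimate: vapour pressure, humidity gap-filling, wind profiles.

Records carry photosynthetically active radiation (PAR), air temperature
(``ta``, degC), relative humidity (``rh``, proportion in [0, 1]) and wind
speed (``wind``, m/s) at a sensor height, from which the vapour pressure
deficit ``d_kpa`` is derived.  Humidity sensors often cover only part of a
campaign; missing humidity is reconstructed from its tight negative linear
coupling with air temperature, fitted per sensor height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import TetensConstants

__all__ = [
    "saturation_vapour_pressure",
    "vapour_pressure_deficit",
    "svp_slope",
    "HumidityModel",
    "fit_humidity_model",
    "gap_fill_humidity",
    "wind_at_height",
    "derive",
    "read_microclimate_csv",
    "write_microclimate_csv",
]

#: Minimum paired (ta, rh) observations required to fit one height.
MIN_HUMIDITY_POINTS = 10

#: Predicted humidity is clipped to this range so D stays defined.
RH_CLIP = (0.01, 1.0)


def saturation_vapour_pressure(t_a, k: TetensConstants = TetensConstants()):
    """Saturation vapour pressure e_sat (kPa) from the Tetens curve.

    Parameters
    ----------
    t_a : float or array
        Air temperature, degC.  Must exceed ``-k.c``.
    """
    t_a = np.asarray(t_a, dtype=float)
    if np.any(t_a <= -k.c):
        raise ValueError(f"air temperature must exceed {-k.c} degC")
    out = k.a * np.exp(k.b * t_a / (t_a + k.c))
    return out if out.ndim else float(out)


def vapour_pressure_deficit(t_a, h, k: TetensConstants = TetensConstants()):
    """Vapour pressure deficit D (kPa): D = e_sat(T_A) * (1 - h)."""
    h = np.asarray(h, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("relative humidity must lie in [0, 1]")
    out = saturation_vapour_pressure(t_a, k) * (1.0 - h)
    return out if np.ndim(out) else float(out)


def svp_slope(t_a, k: TetensConstants = TetensConstants()):
    """Slope s (Pa/K) of the saturation curve evaluated at ``t_a``.

    Analytic derivative of the Tetens form:
    s = 1000 * e_sat * b * c / (T_A + c)**2.
    """
    t_a = np.asarray(t_a, dtype=float)
    e = saturation_vapour_pressure(t_a, k)
    out = 1000.0 * np.asarray(e) * k.b * k.c / (t_a + k.c) ** 2
    return out if out.ndim else float(out)


@dataclass
class HumidityModel:
    """Per-height linear reconstruction of relative humidity from T_A.

    ``coefficients`` maps sensor height (m) to (intercept, slope) of the
    OLS fit h = intercept + slope * T_A; ``r_squared`` maps height to the
    fit R^2.
    """

    coefficients: dict = field(default_factory=dict)
    r_squared: dict = field(default_factory=dict)

    def heights(self):
        return sorted(self.coefficients)

    def nearest_height(self, z: float) -> float:
        hs = self.heights()
        if not hs:
            raise ValueError("humidity model has no fitted heights")
        return min(hs, key=lambda h: abs(h - z))

    def predict(self, z, t_a):
        """Predict h at height ``z`` (nearest fitted sensor height)."""
        b0, b1 = self.coefficients[self.nearest_height(float(z))]
        return np.clip(b0 + b1 * np.asarray(t_a, dtype=float), *RH_CLIP)


def fit_humidity_model(records: pd.DataFrame) -> HumidityModel:
    """Fit the per-height h ~ T_A regression on records with measured h.

    Heights with fewer than ``MIN_HUMIDITY_POINTS`` paired observations, or
    with zero temperature variance, are refused with a warning rather than
    fitted.
    """
    model = HumidityModel()
    usable = records.dropna(subset=["ta", "rh"])
    for z, grp in usable.groupby("height_m"):
        if len(grp) < MIN_HUMIDITY_POINTS:
            warnings.warn(
                f"height {z} m: only {len(grp)} paired (ta, rh) points; "
                "humidity fit refused", stacklevel=2)
            continue
        x = grp["ta"].to_numpy(float)
        y = grp["rh"].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"height {z} m: zero temperature variance; fit refused",
                stacklevel=2)
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        model.coefficients[float(z)] = (float(intercept), float(slope))
        model.r_squared[float(z)] = float(r2)
    return model


def gap_fill_humidity(records: pd.DataFrame, model: HumidityModel,
                      k: TetensConstants = TetensConstants()) -> pd.DataFrame:
    """Fill missing humidity from the T_A regression and recompute D.

    Measured values are untouched; filled values are flagged via
    ``h_source`` in {"measured", "gap_filled"} and clipped to physical
    range so the derived D stays non-negative.
    """
    if not model.coefficients:
        raise ValueError("humidity model has no fitted heights")
    out = records.copy()
    if "h_source" not in out.columns:
        out["h_source"] = "measured"
    missing = out["rh"].isna()
    if missing.any():
        for z, idx in out.loc[missing].groupby("height_m").groups.items():
            out.loc[idx, "rh"] = model.predict(z, out.loc[idx, "ta"])
        out.loc[missing, "h_source"] = "gap_filled"
    out["d_kpa"] = vapour_pressure_deficit(out["ta"].to_numpy(float),
                                           out["rh"].to_numpy(float), k)
    return out


def wind_at_height(profile, z: float) -> float:
    """Wind speed at height ``z`` by linear interpolation within a profile.

    ``profile`` is an iterable of (height_m, wind) pairs.  Outside the
    sensor span the nearest sensor's value is returned (clamped, never
    extrapolated, so speeds stay non-negative).
    """
    pts = sorted((float(h), float(u)) for h, u in profile)
    if not pts:
        raise ValueError("empty wind profile")
    hs = np.array([p[0] for p in pts])
    us = np.array([p[1] for p in pts])
    return float(np.interp(z, hs, us))


def derive(records: pd.DataFrame, model: HumidityModel | None = None,
           k: TetensConstants = TetensConstants()) -> pd.DataFrame:
    """Derive D for a wide-format record table, optionally gap-filling h.

    With a fitted :class:`HumidityModel`, missing humidity is reconstructed
    first; otherwise rows with missing humidity keep a missing D.
    """
    if model is not None:
        return gap_fill_humidity(records, model, k)
    out = records.copy()
    if "h_source" not in out.columns:
        out["h_source"] = np.where(out["rh"].isna(), "missing", "measured")
    ok = out["rh"].notna()
    d = np.full(len(out), np.nan)
    d[ok.to_numpy()] = vapour_pressure_deficit(
        out.loc[ok, "ta"].to_numpy(float), out.loc[ok, "rh"].to_numpy(float), k)
    out["d_kpa"] = d
    return out


# ---------------------------------------------------------------------------
# long-format CSV plumbing

_WIDE_VARS = ("par", "ta", "rh", "wind")


def read_microclimate_csv(path) -> pd.DataFrame:
    """Read a long-format microclimate CSV into wide per-record form.

    Expected columns: ``time`` (ISO-8601), ``height_m``, ``variable`` in
    {par, ta, rh, wind}, ``value``.  Multi-logger streams are aligned on
    exact (time, height) keys; records missing a variable carry NaN.
    """
    long = pd.read_csv(path, parse_dates=["time"])
    wide = (long.pivot_table(index=["time", "height_m"], columns="variable",
                             values="value", aggfunc="mean")
                .reindex(columns=list(_WIDE_VARS))
                .reset_index())
    wide.columns.name = None
    return wide


def write_microclimate_csv(records: pd.DataFrame, path) -> None:
    """Write wide records back to long format plus derived columns."""
    value_vars = [v for v in _WIDE_VARS if v in records.columns]
    extra = [c for c in ("d_kpa", "h_source") if c in records.columns]
    long = records.melt(id_vars=["time", "height_m"] + extra,
                        value_vars=value_vars, var_name="variable",
                        value_name="value")
    long.to_csv(path, index=False)
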