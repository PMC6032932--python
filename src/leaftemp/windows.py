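"""Window-based data selection, species contrasts and summary statistics.

Tower PAR sensors do not always represent the radiation actually received
at a leaf surface.  The selection statistic regresses the model-predicted
temperature difference (delta_T_e) on the observed one (delta_T) within
20-minute windows and keeps only windows where the relationship is close
to the identity: slope within 1 +/- 0.3 and intercept within +/- 2 degC.
Surviving records can then be subset by microclimate bins and compared
between species with leaf-level mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "WindowDiagnostics",
    "MicroclimateBin",
    "select_windows",
    "subset_by_microclimate",
    "compare_species",
    "pseudo_r_squared",
    "daily_summaries",
    "regression_through_origin",
    "balanced_par_subsample",
]

#: Acceptance gates on the per-window est-on-obs regression.
SLOPE_BAND = (0.7, 1.3)
INTERCEPT_BAND = (-2.0, 2.0)

#: Default window width (s) and minimum points per window (half the 120
#: possible at the native 10-s cadence).
WINDOW_WIDTH_S = 1200
N_MIN = 60

#: Top-of-canopy PAR threshold defining daytime, umol m-2 s-1.
DAYTIME_PAR = 5.0


@dataclass
class WindowDiagnostics:
    window_start: pd.Timestamp
    leaf_id: str
    slope: float
    intercept: float
    n_points: int
    selected: bool
    reason: str = ""


@dataclass(frozen=True)
class MicroclimateBin:
    """Half-open [lo, hi) ranges on PAR, air temperature and wind speed."""

    label: str
    par_lo: float
    par_hi: float
    ta_lo: float
    ta_hi: float
    u_lo: float
    u_hi: float

    def __post_init__(self) -> None:
        if not (self.par_lo < self.par_hi and self.ta_lo < self.ta_hi
                and self.u_lo < self.u_hi):
            raise ValueError("bin ranges must be non-empty")

    def contains(self, par, ta, u):
        return ((par >= self.par_lo) & (par < self.par_hi)
                & (ta >= self.ta_lo) & (ta < self.ta_hi)
                & (u >= self.u_lo) & (u < self.u_hi))


def select_windows(df: pd.DataFrame, width_s: int = WINDOW_WIDTH_S,
                   n_min: int = N_MIN,
                   slope_band=SLOPE_BAND, intercept_band=INTERCEPT_BAND):
    """Per-window OLS of predicted on observed delta_T with acceptance gates.

    ``df`` needs columns ``time``, ``leaf_id``, ``dt_obs`` and ``dt_est``.
    Windows are aligned to clock boundaries of ``width_s`` seconds.  Within
    each (leaf, window) group, ``dt_est`` is regressed on ``dt_obs``; the
    window is kept when the slope falls in ``slope_band``, the intercept in
    ``intercept_band`` and the group has at least ``n_min`` points.

    Returns ``(diagnostics, mask)``: a list of :class:`WindowDiagnostics`
    and a boolean Series over ``df`` marking records of selected windows.
    """
    t = pd.to_datetime(df["time"])
    epoch = t.astype("int64") // 10**9
    win = (epoch // width_s) * width_s
    x = df["dt_obs"].to_numpy(float)
    y = df["dt_est"].to_numpy(float)

    g = pd.DataFrame({"leaf_id": df["leaf_id"].to_numpy(), "win": win.to_numpy(),
                      "x": x, "y": y, "xy": x * y, "xx": x * x})
    agg = g.groupby(["leaf_id", "win"]).agg(
        n=("x", "size"), sx=("x", "sum"), sy=("y", "sum"),
        sxy=("xy", "sum"), sxx=("xx", "sum"))

    n = agg["n"].to_numpy(float)
    sx, sy = agg["sx"].to_numpy(), agg["sy"].to_numpy()
    var = agg["sxx"].to_numpy() - sx**2 / n
    cov = agg["sxy"].to_numpy() - sx * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), np.nan)
    intercept = sy / n - slope * sx / n

    diags = []
    selected_keys = set()
    for (key, ni, sl, ic) in zip(agg.index, n, slope, intercept):
        leaf, w0 = key
        if ni < n_min:
            sel, reason = False, f"n={int(ni)} < n_min={n_min}"
        elif not np.isfinite(sl):
            sel, reason = False, "degenerate (zero obs variance)"
        elif not (slope_band[0] <= sl <= slope_band[1]):
            sel, reason = False, "slope outside band"
        elif not (intercept_band[0] <= ic <= intercept_band[1]):
            sel, reason = False, "intercept outside band"
        else:
            sel, reason = True, ""
        if sel:
            selected_keys.add(key)
        diags.append(WindowDiagnostics(
            window_start=pd.Timestamp(w0, unit="s"), leaf_id=leaf,
            slope=float(sl) if np.isfinite(sl) else np.nan,
            intercept=float(ic) if np.isfinite(ic) else np.nan,
            n_points=int(ni), selected=sel, reason=reason))

    keys = pd.MultiIndex.from_arrays([df["leaf_id"], win], names=["leaf_id", "win"])
    mask = pd.Series(keys.isin(selected_keys), index=df.index)
    return diags, mask


def subset_by_microclimate(records: pd.DataFrame, bin: MicroclimateBin) -> pd.DataFrame:
    """Rows of a selected, leaf-joined record table inside one bin.

    ``records`` needs columns ``par``, ``ta``, ``wind``; any prior
    window-selection mask should already have been applied.
    """
    keep = bin.contains(records["par"].to_numpy(float),
                        records["ta"].to_numpy(float),
                        records["wind"].to_numpy(float))
    return records.loc[keep]


def compare_species(subset: pd.DataFrame, response: str = "dt_obs"):
    """Species contrast on delta_T with a leaf random intercept.

    Fits ``response ~ species`` (two species) with leaf as random factor
    and returns ``(difference, se, p, fit)`` for the second species
    relative to the first (alphabetical).  Falls back to OLS with a
    warning when the random intercept is unidentifiable.
    """
    species = sorted(subset["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least two species to contrast")
    leaves = subset.groupby("species")["leaf_id"].nunique()
    if (leaves < 2).any():
        raise ValueError("need at least two leaves per species")
    df = subset.copy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(f"{response} ~ C(species)", df,
                              groups=df["leaf_id"]).fit(reml=True)
        key = [k for k in fit.fe_params.index if k.startswith("C(species)")][0]
        return (float(fit.fe_params[key]), float(fit.bse_fe[key]),
                float(fit.pvalues[key]), fit)
    except Exception:
        warnings.warn("mixed species contrast failed; falling back to OLS",
                      stacklevel=2)
        fit = smf.ols(f"{response} ~ C(species)", df).fit()
        key = [k for k in fit.params.index if k.startswith("C(species)")][0]
        return (float(fit.params[key]), float(fit.bse[key]),
                float(fit.pvalues[key]), fit)


def pseudo_r_squared(fit):
    """Marginal and conditional pseudo R^2 of a fitted mixed model.

    Variance-partition form: the marginal value is the fixed-effect share
    of the total (fixed + random + residual) variance; the conditional
    value adds the random-intercept share.
    """
    fixed = np.asarray(fit.model.exog) @ np.asarray(fit.fe_params)
    var_f = float(np.var(fixed))
    var_r = float(np.asarray(fit.cov_re).ravel()[0]) if fit.k_re else 0.0
    var_e = float(fit.scale)
    total = var_f + var_r + var_e
    return var_f / total, (var_f + var_r) / total


def daily_summaries(series: pd.DataFrame, daytime: pd.Series | None = None,
                    value_cols=("dt_obs",)) -> pd.DataFrame:
    """Min/mean/max/skewness per leaf for day and night records.

    ``daytime`` is a boolean Series aligned with ``series``; when omitted,
    rows with top-of-canopy ``par`` above :data:`DAYTIME_PAR` are daytime.
    Skewness is the adjusted Fisher-Pearson sample statistic; it is
    reported missing for constant series.
    """
    df = series.copy()
    if daytime is None:
        df["_day"] = df["par"].to_numpy(float) > DAYTIME_PAR
    else:
        df["_day"] = daytime.to_numpy(bool)
    rows = []
    for (leaf, day), grp in df.groupby(["leaf_id", "_day"]):
        row = {"leaf_id": leaf, "period": "day" if day else "night",
               "n": len(grp)}
        for col in value_cols:
            v = grp[col].dropna().to_numpy(float)
            row[f"{col}_min"] = v.min() if len(v) else np.nan
            row[f"{col}_mean"] = v.mean() if len(v) else np.nan
            row[f"{col}_max"] = v.max() if len(v) else np.nan
            row[f"{col}_skew"] = (float(stats.skew(v, bias=False))
                                  if len(v) > 2 and np.ptp(v) > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def regression_through_origin(x, y, alpha: float = 0.05):
    """No-intercept OLS slope with its confidence interval.

    slope = sum(xy) / sum(x^2); the CI comes from the no-intercept model's
    t distribution.  Returns ``(slope, (lo, hi))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == 0):
        raise ValueError("all x are zero; slope through origin undefined")
    fit = sm.OLS(y, x[:, None]).fit()
    lo, hi = fit.conf_int(alpha=alpha)[0]
    return float(fit.params[0]), (float(lo), float(hi))


def balanced_par_subsample(records: pd.DataFrame, rng,
                           bin_width: float = 250.0, n_per_bin: int = 1000,
                           par_max: float = 1000.0) -> pd.DataFrame:
    """Balance sampling density across PAR bins below ``par_max``.

    Bins of ``bin_width`` umol m-2 s-1 below ``par_max`` are capped at
    ``n_per_bin`` randomly chosen rows; brighter records pass unchanged.
    """
    par = records["par"].to_numpy(float)
    keep_idx = []
    below = par < par_max
    bins = np.floor(par[below] / bin_width).astype(int)
    idx_below = records.index[below]
    for b in np.unique(bins):
        idx = idx_below[bins == b]
        if len(idx) > n_per_bin:
            idx = rng.choice(idx, size=n_per_bin, replace=False)
        keep_idx.extend(idx)
    keep_idx.extend(records.index[~below])
    return records.loc[sorted(keep_idx)]
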