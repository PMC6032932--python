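"""Recalibration of the boundary-layer conductance from inverted resistances.

The flat-plate coefficient in g_b,H = a * (U/W)**b overpredicts resistance
at low within-canopy wind speeds.  Given boundary-layer resistances to
water recovered by inverting the energy balance against observed leaf
temperatures, this module re-estimates ``a`` (one-parameter model, b fixed
at 0.5) or both ``a`` and ``b`` (two-parameter model) by nonlinear least
squares on the resistance scale:

    r_bW(U, W) = 1 / (water_ratio * a * (U/W)**b)

Binned summaries (0.1 m/s wind bins with per-bin outlier fences and a
PAR >= 200 umol m-2 s-1 screen) are provided for display and diagnostics;
the fit itself uses raw points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import BoundaryLayerParams

__all__ = ["CalibrationFit", "bin_resistances", "fit_boundary_constants"]

#: Low-light screen for inverted resistances, umol m-2 s-1.
PAR_MIN = 200.0

#: Tukey fence multiplier for per-bin outlier exclusion.
TUKEY_K = 1.5


@dataclass
class CalibrationFit:
    model: str            # "one_param" | "two_param"
    a: float              # m s^-1/2
    a_se: float
    b: float              # exponent (0.5 fixed for one_param)
    b_se: Optional[float]
    n_points: int
    residual_sd: float


def bin_resistances(records: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Per-wind-bin mean/SD of inverted r_bW with exclusions applied.

    ``records`` needs columns ``u`` (m/s), ``r_b_w`` (s/m) and ``par``.
    Rows with PAR < 200 are dropped; within each half-open bin
    [k*width, (k+1)*width), points outside the Tukey fences
    (1.5 x IQR beyond the quartiles) are excluded.  Returns a frame with
    ``u_bin`` (left edge), ``mean``, ``sd``, ``n``.
    """
    if len(records) == 0:
        raise ValueError("empty resistance stream")
    ok = records.loc[records["par"] >= PAR_MIN].dropna(subset=["r_b_w"])
    if "flag" in ok.columns:
        ok = ok.loc[ok["flag"].isin(["ok", "multi_root"])]
    rows = []
    if len(ok):
        bins = np.floor(ok["u"].to_numpy(float) / bin_width).astype(int)
        for k, grp in ok.groupby(bins):
            v = grp["r_b_w"].to_numpy(float)
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            keep = v[(v >= q1 - TUKEY_K * iqr) & (v <= q3 + TUKEY_K * iqr)]
            rows.append({"u_bin": k * bin_width, "mean": keep.mean(),
                         "sd": keep.std(ddof=1) if len(keep) > 1 else 0.0,
                         "n": len(keep)})
    return pd.DataFrame(rows, columns=["u_bin", "mean", "sd", "n"])


def tukey_keep_mask(u, r_b_w, bin_width: float = 0.1) -> np.ndarray:
    """Boolean mask of points inside the per-wind-bin Tukey fences.

    The same 1.5 x IQR rule :func:`bin_resistances` applies for display,
    exposed as a mask so raw-point fits can use the identical exclusion.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(r_b_w, dtype=float)
    keep = np.zeros(len(v), dtype=bool)
    finite = np.isfinite(v) & np.isfinite(u)
    bins = np.full(len(v), -1)
    bins[finite] = np.floor(u[finite] / bin_width).astype(int)
    for k in np.unique(bins[finite]):
        idx = np.flatnonzero(bins == k)
        q1, q3 = np.percentile(v[idx], [25, 75])
        iqr = q3 - q1
        keep[idx] = (v[idx] >= q1 - TUKEY_K * iqr) & (v[idx] <= q3 + TUKEY_K * iqr)
    return keep


def fit_boundary_constants(u, w, r_b_w, model: str = "one_param",
                           p: BoundaryLayerParams = BoundaryLayerParams(),
                           on_conductance: bool = False,
                           max_iter: int = 200) -> CalibrationFit:
    """Nonlinear least squares for the boundary-layer constants.

    Parameters
    ----------
    u, w, r_b_w : arrays
        Wind speed (m/s), leaf width (m) and inverted boundary-layer
        resistance to water (s/m).
    model : {"one_param", "two_param"}
        ``one_param`` fits the coefficient ``a`` with the exponent fixed at
        0.5; ``two_param`` fits both.
    on_conductance : bool
        Fit on the conductance scale 1/r instead of the default resistance
        scale.
    """
    u, w, y = np.broadcast_arrays(np.asarray(u, dtype=float),
                                  np.asarray(w, dtype=float),
                                  np.asarray(r_b_w, dtype=float))
    ok = np.isfinite(u) & np.isfinite(w) & np.isfinite(y) & (u > 0) & (w > 0)
    u, w, y = u[ok], w[ok], y[ok]
    if len(y) < 5:
        raise ValueError("need at least 5 valid points to calibrate")

    ratio = u / w
    wr = p.water_ratio

    if on_conductance:
        y = 1.0 / y
        def f1(x, a):
            return wr * a * x**0.5
        def f2(x, a, b):
            return wr * a * x**b
    else:
        def f1(x, a):
            return 1.0 / (wr * a * x**0.5)
        def f2(x, a, b):
            return 1.0 / (wr * a * x**b)

    try:
        if model == "one_param":
            popt, pcov = curve_fit(f1, ratio, y, p0=[0.0105], maxfev=max_iter * 10)
            a, b = float(popt[0]), 0.5
            a_se, b_se = float(np.sqrt(pcov[0, 0])), None
            pred = f1(ratio, a)
        elif model == "two_param":
            popt, pcov = curve_fit(f2, ratio, y, p0=[0.0105, 0.5],
                                   maxfev=max_iter * 10)
            a, b = float(popt[0]), float(popt[1])
            se = np.sqrt(np.diag(pcov))
            a_se, b_se = float(se[0]), float(se[1])
            pred = f2(ratio, a, b)
        else:
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError as exc:  # curve_fit non-convergence
        raise RuntimeError(
            f"boundary-constant fit ({model}) did not converge on "
            f"{len(y)} points: {exc}") from exc

    resid = y - pred
    dof = max(len(y) - (1 if model == "one_param" else 2), 1)
    return CalibrationFit(model=model, a=a, a_se=a_se, b=b, b_se=b_se,
                          n_points=int(len(y)),
                          residual_sd=float(np.sqrt(np.sum(resid**2) / dof)))
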