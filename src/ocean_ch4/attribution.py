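"""What drives the dCH4 distribution: correlations, fits, band averages.

Reproduces the analysis layer of the pipeline: per-predictor R^2 against the
mapped annual-mean dCH4 split at the 2000 m isobath, the coastal depth
power law (binned log-log fit), the open-ocean NPP linear fit and NPP+PO4
multiple regression, and area-weighted latitudinal band averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

COASTAL_DEPTH_M = 2000.0

#: Latitude band edges for large-scale averages.
BANDS = {
    "tropical": (0.0, 15.0),
    "subtropical": (15.0, 45.0),
    "subpolar": (45.0, 60.0),
    "polar": (60.0, 90.0),
}


def _r_squared(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def predictor_correlations(mean_map: xr.DataArray, predictors: xr.Dataset,
                           region: str = "coastal",
                           predictor_names=None,
                           transforms=("identity", "logy", "loglog")) -> pd.DataFrame:
    """R^2 of annual-mean dCH4 against each predictor, per transform.

    ``region`` selects cells by the 2000 m isobath ('coastal' or 'open').
    Log variants exclude non-positive dCH4 (and non-positive predictor values
    for log-log); the exclusion count is reported per row.
    """
    depth = predictors["depth_m"].values
    if region == "coastal":
        sel = depth < COASTAL_DEPTH_M
    elif region == "open":
        sel = depth >= COASTAL_DEPTH_M
    else:
        raise ValueError("region must be 'coastal' or 'open'")
    dch4 = np.asarray(mean_map)[sel]
    ok = np.isfinite(dch4)
    if not ok.any():
        raise ValueError(f"no finite dCH4 cells in {region} subset")
    if predictor_names is None:
        predictor_names = ["depth_m", "sst_C", "sss_psu", "npp", "poc_export",
                           "po4_uM", "o2_uM", "hydrate", "dms_nM"]
        predictor_names = [p for p in predictor_names if p in predictors]
    rows = []
    for name in predictor_names:
        pv = predictors[name].values[sel]
        for tr in transforms:
            y, x = dch4.copy(), pv.copy()
            keep = ok & np.isfinite(x)
            if tr in ("logy", "loglog"):
                keep &= y > 0
            if tr == "loglog":
                keep &= x > 0
            excluded = int(ok.sum() - keep.sum())
            yy = np.log10(y[keep]) if tr in ("logy", "loglog") else y[keep]
            xx = np.log10(x[keep]) if tr == "loglog" else x[keep]
            rows.append({"predictor": name, "transform": tr,
                         "r2": _r_squared(xx, yy), "n": int(keep.sum()),
                         "excluded": excluded})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binned fits
# ---------------------------------------------------------------------------

def _binned_means(x, y, edges):
    idx = np.digitize(x, edges) - 1
    xm, ym = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            xm.append(x[m].mean())
            ym.append(y[m].mean())
    return np.array(xm), np.array(ym)


def powerlaw_fit(dch4, depth, n_bins: int = 12,
                 depth_range=(10.0, 2000.0)) -> dict:
    """Fit dCH4 = A * z^b by binned log-log least squares.

    Observations are binned in ``n_bins`` log-spaced depth bins; the fit is
    log10(mean dCH4) vs log10(mean depth) by OLS.  Non-positive binned means
    are excluded and counted.
    """
    dch4 = np.asarray(dch4, float)
    depth = np.asarray(depth, float)
    edges = np.logspace(np.log10(depth_range[0]), np.log10(depth_range[1]),
                        n_bins + 1)
    zm, ym = _binned_means(depth, dch4, edges)
    pos = ym > 0
    n_excluded = int((~pos).sum())
    zm, ym = zm[pos], ym[pos]
    if zm.size < 3:
        raise ValueError("fewer than 3 non-empty positive depth bins")
    if np.ptp(ym) == 0:
        return {"amplitude": float(ym[0]), "exponent": 0.0, "r2": np.nan,
                "n_bins": int(zm.size), "excluded_bins": n_excluded}
    x = sm.add_constant(np.log10(zm))
    fit = sm.OLS(np.log10(ym), x).fit()
    return {
        "amplitude": float(10 ** fit.params[0]),
        "exponent": float(fit.params[1]),
        "r2": float(fit.rsquared),
        "n_bins": int(zm.size),
        "excluded_bins": n_excluded,
    }


def npp_fit(dch4, npp, n_bins: int = 12) -> dict:
    """Binned linear fit dCH4 = slope * NPP + intercept (slope in nM units)."""
    dch4 = np.asarray(dch4, float)
    npp = np.asarray(npp, float)
    edges = np.linspace(npp.min(), npp.max() * (1 + 1e-9), n_bins + 1)
    xm, ym = _binned_means(npp, dch4, edges)
    if xm.size < 3:
        raise ValueError("fewer than 3 non-empty NPP bins")
    x = sm.add_constant(xm)
    fit = sm.OLS(ym, x).fit()
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared), "n_bins": int(xm.size)}


def mlr_fit(dch4, npp, po4) -> dict:
    """Unbinned multiple regression dCH4 ~ NPP + PO4 on open-ocean rows."""
    dch4 = np.asarray(dch4, float)
    npp = np.asarray(npp, float)
    po4 = np.asarray(po4, float)
    if abs(np.corrcoef(npp, po4)[0, 1]) > 0.99:
        warnings.warn("NPP and PO4 nearly collinear; coefficients unstable")
    x = sm.add_constant(np.column_stack([npp, po4]))
    fit = sm.OLS(dch4, x).fit()
    return {"intercept": float(fit.params[0]), "npp_coeff": float(fit.params[1]),
            "po4_coeff": float(fit.params[2]), "r2": float(fit.rsquared)}


# ---------------------------------------------------------------------------
# Latitudinal band averages
# ---------------------------------------------------------------------------

def band_averages(mean_map: xr.DataArray, predictors: xr.Dataset,
                  fields=("npp",), bands: dict | None = None,
                  open_ocean_only: bool = True) -> pd.DataFrame:
    """Area-weighted means of dCH4 and predictors per latitude band."""
    bands = bands or BANDS
    lat = predictors["lat"].values[:, None]
    area = predictors["cell_area"].values
    depth = predictors["depth_m"].values
    dch4 = np.asarray(mean_map)
    sel_base = np.isfinite(dch4)
    if open_ocean_only:
        sel_base &= depth >= COASTAL_DEPTH_M
    rows = []
    for name, (lo, hi) in bands.items():
        sel = sel_base & (np.abs(np.broadcast_to(lat, dch4.shape)) >= lo) \
            & (np.abs(np.broadcast_to(lat, dch4.shape)) < hi)
        if not sel.any():
            rows.append({"band": name, "dch4_nM": np.nan, "area_m2": 0.0,
                         "flagged_empty": True})
            continue
        w = area[sel]
        row = {"band": name,
               "dch4_nM": float(np.average(dch4[sel], weights=w)),
               "area_m2": float(w.sum()), "flagged_empty": False}
        for f in fields:
            row[f] = float(np.average(predictors[f].values[sel], weights=w))
        rows.append(row)
    return pd.DataFrame(rows)


def attribution_report(mean_map: xr.DataArray, predictors: xr.Dataset) -> dict:
    """Full attribution analysis bundle on an annual-mean map."""
    depth = predictors["depth_m"].values
    dch4 = np.asarray(mean_map)
    coastal = (depth < COASTAL_DEPTH_M) & np.isfinite(dch4)
    open_ = (depth >= COASTAL_DEPTH_M) & np.isfinite(dch4)
    out = {
        "coastal_correlations": predictor_correlations(mean_map, predictors, "coastal"),
        "open_correlations": predictor_correlations(mean_map, predictors, "open"),
        "powerlaw": powerlaw_fit(dch4[coastal], depth[coastal]),
        "npp": npp_fit(dch4[open_], predictors["npp"].values[open_]),
        "mlr": mlr_fit(dch4[open_], predictors["npp"].values[open_],
                       predictors["po4_uM"].values[open_]),
        "bands": band_averages(mean_map, predictors),
    }
    return out
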