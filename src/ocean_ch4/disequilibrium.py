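"""Methane disequilibrium: from raw shipboard [CH4] to a gridded climatology.

The surface-ocean methane disequilibrium is

    dCH4 = [CH4] - S_CH4 * pCH4_moist                                (nM)

where S_CH4(T, S) is the atmospheric-equilibrium solubility and pCH4_moist is
the moist-air methane partial pressure obtained by kriging station dry-air
records to the observation point and applying a water-vapor correction.
Records are filtered to the mixed layer and the 1980-2016 window, then binned
into a monthly lat/lon climatology (all years pooled per calendar month).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import constants as c
from .grid import bin_indices, make_grid, region_mask

OBS_COLUMNS = [
    "lat", "lon", "date", "depth_m", "temperature_C", "salinity_psu", "ch4_nM",
]

DATE_WINDOW = (pd.Timestamp("1980-01-01"), pd.Timestamp("2016-12-31"))


# ---------------------------------------------------------------------------
# Solubility and moist-air correction
# ---------------------------------------------------------------------------

def solubility(temperature_C, salinity):
    """Equilibrium [CH4] per unit pCH4 [nM ppb^-1] from T [C] and S [psu].

    Evaluates the Wiesenburg & Guinasso (1979) atmospheric-equilibrium fit
    ln C = ln f + A1 + A2 (100/T) + A3 ln(T/100) + A4 (T/100)
    + S [B1 + B2 (T/100) + B3 (T/100)^2] with f = 1 ppb.
    """
    t = np.asarray(temperature_C, dtype=float)
    s = np.asarray(salinity, dtype=float)
    tlo, thi = c.SOLUBILITY_T_RANGE_C
    slo, shi = c.SOLUBILITY_S_RANGE
    if np.any(t < tlo) or np.any(t > thi):
        raise ValueError(f"temperature outside solubility range [{tlo}, {thi}] C")
    if np.any(s < slo) or np.any(s > shi):
        raise ValueError(f"salinity outside solubility range [{slo}, {shi}]")
    k = c.WG79_CH4_NMOL_PER_L
    tk = t + 273.15
    t100 = tk / 100.0
    ln_c = (
        np.log(1e-9)
        + k["A1"]
        + k["A2"] * (100.0 / tk)
        + k["A3"] * np.log(t100)
        + k["A4"] * t100
        + s * (k["B1"] + k["B2"] * t100 + k["B3"] * t100**2)
    )
    out = np.exp(ln_c)
    return out if out.ndim else float(out)


def vapor_pressure_seawater(temperature_C, salinity):
    """Saturation water-vapor pressure over seawater [atm] (Weiss & Price 1980)."""
    t = np.asarray(temperature_C, dtype=float)
    s = np.asarray(salinity, dtype=float)
    k = c.WP80_VAPOR_PRESSURE
    tk = t + 273.15
    ln_e = k["c0"] + k["c1"] * (100.0 / tk) + k["c2"] * np.log(tk / 100.0) + k["cs"] * s
    out = np.exp(ln_e)
    return out if out.ndim else float(out)


def moist_correction(p_dry_ppb, temperature_C, salinity):
    """Convert dry-air pCH4 [ppb] to moist-air pCH4 at 1 atm total pressure."""
    p = np.asarray(p_dry_ppb, dtype=float)
    if np.any(p <= 0):
        raise ValueError("dry pCH4 must be positive")
    e_w = vapor_pressure_seawater(temperature_C, salinity)
    out = p * (1.0 - e_w)  # total pressure fixed at 1 atm
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Atmospheric stations and ordinary kriging
# ---------------------------------------------------------------------------

def _haversine_km(lat1, lon1, lat2, lon2):
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * c.EARTH_RADIUS_M / 1000.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def exponential_variogram(h_km, range_km=3000.0, sill=1.0, nugget=0.0):
    """gamma(h) = nugget + sill * (1 - exp(-h/range))."""
    return nugget + sill * (1.0 - np.exp(-np.asarray(h_km, float) / range_km))


class AtmosphericField:
    """Station dry-air pCH4 series with ordinary-kriging interpolation.

    Parameters
    ----------
    stations : DataFrame with columns station_id, lat, lon, year, month,
        pch4_ppb.
    variogram_range_km : range of the exponential variogram (atmospheric CH4
        is smooth at monthly scale, so a long default range is used).
    """

    def __init__(self, stations: pd.DataFrame, variogram_range_km: float = 3000.0,
                 nugget: float = 0.0):
        self.stations = stations.copy()
        self.range_km = variogram_range_km
        self.nugget = nugget
        meta = stations[["station_id", "lat", "lon"]].drop_duplicates("station_id")
        self._ids = meta["station_id"].to_numpy()
        self._lat = meta["lat"].to_numpy(float)
        self._lon = meta["lon"].to_numpy(float)
        self._series = {
            (int(r.year), int(r.month), r.station_id): float(r.pch4_ppb)
            for r in stations.itertuples()
        }
        self._weight_cache: dict[tuple[float, float, tuple], np.ndarray] = {}

    def _kriging_weights(self, lat: float, lon: float, active: np.ndarray):
        key = (round(lat, 6), round(lon, 6), tuple(active))
        w = self._weight_cache.get(key)
        if w is not None:
            return w
        slat, slon = self._lat[active], self._lon[active]
        n = slat.size
        if n == 1:
            w = np.array([1.0])
        else:
            h = _haversine_km(slat[:, None], slon[:, None], slat[None, :], slon[None, :])
            gamma = exponential_variogram(h, self.range_km, nugget=self.nugget)
            np.fill_diagonal(gamma, 0.0)
            a = np.zeros((n + 1, n + 1))
            a[:n, :n] = gamma
            a[n, :n] = 1.0
            a[:n, n] = 1.0
            g0 = exponential_variogram(
                _haversine_km(slat, slon, lat, lon), self.range_km, nugget=self.nugget
            )
            # exact interpolation at station locations
            g0 = np.where(
                _haversine_km(slat, slon, lat, lon) < 1e-6, 0.0, g0
            )
            b = np.concatenate([g0, [1.0]])
            w = np.linalg.solve(a, b)[:n]
        self._weight_cache[key] = w
        return w

    def dry_pch4(self, lat: float, lon: float, year: int, month: int) -> float:
        """Ordinary-kriging estimate of dry pCH4 [ppb] at a point and month."""
        vals, active = [], []
        for i, sid in enumerate(self._ids):
            v = self._series.get((int(year), int(month), sid))
            if v is not None:
                vals.append(v)
                active.append(i)
        if not vals:
            raise KeyError(f"no station data for {year}-{month:02d}")
        w = self._kriging_weights(float(lat), float(lon), np.array(active))
        return float(w @ np.asarray(vals))

    def moist_pch4(self, lat, lon, year, month, temperature_C, salinity) -> float:
        return float(
            moist_correction(self.dry_pch4(lat, lon, year, month),
                             temperature_C, salinity)
        )


# ---------------------------------------------------------------------------
# Record filtering and the disequilibrium calculation
# ---------------------------------------------------------------------------

def mixed_layer_filter(records: pd.DataFrame, mld,
                       salinity_fill=None,
                       allow_missing_temperature_sources: tuple = ()) -> pd.DataFrame:
    """Retain records sampled within the mixed layer and the date window.

    ``mld(lat, lon, month)`` returns the climatological mixed-layer depth [m].
    Missing salinity is filled from ``salinity_fill(lat, lon)`` and flagged;
    records missing temperature are dropped unless their ``source`` is in the
    allow-list.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    month = df["date"].dt.month.to_numpy()
    in_window = (df["date"] >= DATE_WINDOW[0]) & (df["date"] <= DATE_WINDOW[1])
    mld_at = np.array(
        [mld(la, lo, m) for la, lo, m in
         zip(df["lat"].to_numpy(), df["lon"].to_numpy(), month)]
    )
    keep = in_window.to_numpy() & (df["depth_m"].to_numpy() <= mld_at)

    t_missing = df["temperature_C"].isna().to_numpy()
    if "source" in df.columns:
        exempt = df["source"].isin(allow_missing_temperature_sources).to_numpy()
    else:
        exempt = np.zeros(len(df), bool)
    keep &= ~t_missing | exempt

    out = df.loc[keep].copy()
    s_missing = out["salinity_psu"].isna()
    out["salinity_filled"] = s_missing
    if s_missing.any():
        if salinity_fill is None:
            raise ValueError("records with missing salinity but no fill climatology")
        out.loc[s_missing, "salinity_psu"] = [
            salinity_fill(la, lo)
            for la, lo in out.loc[s_missing, ["lat", "lon"]].to_numpy()
        ]
    return out.reset_index(drop=True)


def delta_ch4(records: pd.DataFrame, atmosphere: AtmosphericField) -> pd.DataFrame:
    """Append dCH4 [nM] = [CH4] - S_CH4 * pCH4_moist to filtered records."""
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    p_moist = np.array(
        [
            atmosphere.moist_pch4(r.lat, r.lon, r.date.year, r.date.month,
                                  r.temperature_C, r.salinity_psu)
            for r in df.itertuples()
        ]
    )
    s_ch4 = solubility(df["temperature_C"].to_numpy(), df["salinity_psu"].to_numpy())
    df["pch4_moist_ppb"] = p_moist
    df["dch4_nM"] = df["ch4_nM"].to_numpy() - np.asarray(s_ch4) * p_moist
    return df


def perturb_measurements(records: pd.DataFrame, relative_error: float,
                         seed: int) -> pd.DataFrame:
    """Uniform multiplicative perturbation of [CH4] in (1-RE, 1+RE)."""
    if not 0 <= relative_error < 1:
        raise ValueError("relative error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = records.copy()
    factors = rng.uniform(1 - relative_error, 1 + relative_error, len(df))
    df["ch4_nM"] = df["ch4_nM"].to_numpy() * factors
    return df


# ---------------------------------------------------------------------------
# Monthly climatology
# ---------------------------------------------------------------------------

def bin_climatology(records: pd.DataFrame, resolution: float,
                    lat_extent: tuple[float, float],
                    lon_extent: tuple[float, float],
                    depth_field: xr.DataArray | None = None) -> xr.Dataset:
    """Bin per-record dCH4 into a monthly mean climatology.

    Cells with no observations are NaN with count 0 (missing, not zero).
    """
    grid = make_grid(resolution, lat_extent, lon_extent)
    nlat, nlon = grid["lat"].size, grid["lon"].size
    total = np.zeros((12, nlat, nlon))
    count = np.zeros((12, nlat, nlon), dtype=np.int64)

    df = records
    month = pd.to_datetime(df["date"]).dt.month.to_numpy() - 1
    i, j, ok = bin_indices(df["lat"].to_numpy(), df["lon"].to_numpy(), grid)
    vals = df["dch4_nM"].to_numpy()
    np.add.at(total, (month[ok], i[ok], j[ok]), vals[ok])
    np.add.at(count, (month[ok], i[ok], j[ok]), 1)

    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)

    ds = grid.copy()
    ds["dch4_nM"] = (("month", "lat", "lon"), mean, {"units": "nM"})
    ds["count"] = (("month", "lat", "lon"), count)
    ds = ds.assign_coords(month=np.arange(1, 13))
    if depth_field is not None:
        depth = depth_field.interp(lat=ds["lat"], lon=ds["lon"], method="nearest")
        ds["depth_m"] = (("lat", "lon"), depth.values, {"units": "m"})
        ds["region"] = (("lat", "lon"), region_mask(depth.values))
    return ds


def annual_mean(climatology: xr.Dataset) -> xr.DataArray:
    """Count-weighted annual mean dCH4 over the months present per cell."""
    total = (climatology["dch4_nM"].fillna(0.0) * climatology["count"]).sum("month")
    n = climatology["count"].sum("month")
    return xr.where(n > 0, total / n, np.nan)
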