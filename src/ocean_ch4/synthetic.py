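"""Synthetic ocean world emulating the statistical structure of the study data.

Generates every input the emission pipeline needs: a closed-basin bathymetry,
predictor climatologies, a dCH4 truth field built from the two observed
relationships (coastal power law in seafloor depth, open-ocean linear relation
to net primary production), cruise-track observations with multiplicative
lognormal noise, atmospheric station series, multi-product wind and sea-ice
climatologies, and a volume-weighted bubble size spectrum.

Everything is deterministic under the configured seed.  The truth relations
use the observation-derived binned fits (dCH4 = 69 z^-0.8 nM on the shelf and
slope; dCH4 = (0.3 NPP + 14)/1e3 nM in the open ocean).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import grid as gridmod
from .disequilibrium import AtmosphericField, solubility, moist_correction


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) by hashing the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class SyntheticWorldConfig:
    """Knobs of the synthetic world; defaults are the package's study conditions."""

    resolution: float = 0.5                 # degrees
    lat_extent: tuple = (-70.0, 70.0)
    lon_extent: tuple = (0.0, 40.0)
    n_tracks: int = 60
    obs_per_track: int = 40
    noise_sigma: float = 0.5                # lognormal sigma (ln-space, unit mean)
    below_mld_fraction: float = 0.15
    out_of_window_fraction: float = 0.05
    coastal_amplitude: float = 69.0         # nM at 1 m
    coastal_exponent: float = -0.8
    npp_slope: float = 0.3                  # 1e-3 nM per (mg C m-2 d-1)
    npp_intercept: float = 14.0             # 1e-3 nM
    open_po4_coeff: float = 0.0             # nM per uM, optional MLR term
    polar_undersaturation: float = 0.12     # nM drawdown south of polar_lat
    polar_lat: float = -55.0
    atm_baseline_ppb: float = 1650.0        # at 1980.0
    atm_trend_ppb_yr: float = 200.0 / 37.0  # reaches ~1850 ppb by end of 2016
    atm_seasonal_amp_ppb: float = 15.0
    atm_gradient_ppb: float = 30.0          # interhemispheric contrast
    n_wind_products: int = 5
    wind_perturbation_scale: float = 0.10
    n_ice_products: int = 3
    ice_lat_threshold: float = 60.0
    bubble_mean_diameter_mm: float = 4.0
    bubble_sigma_ln: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.coastal_exponent >= 0:
            raise ValueError("coastal exponent must be negative "
                             "(dCH4 decreases with depth)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticWorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Grid, bathymetry, predictors, truth
# ---------------------------------------------------------------------------

SHELF_WIDTH_DEG = 8.0    # linear 0-200 m: ~uniform shelf hypsometry
SLOPE_WIDTH_DEG = 6.0    # 200-2000 m
MAX_DEPTH_M = 5500.0


def make_grid(config: SyntheticWorldConfig) -> xr.Dataset:
    return gridmod.make_grid(config.resolution, config.lat_extent, config.lon_extent)


def make_bathymetry(config: SyntheticWorldConfig, grid: xr.Dataset) -> xr.Dataset:
    """Depth field deepening monotonically away from the western coastline."""
    ds = grid.copy()
    lon = ds["lon"].values
    lat = ds["lat"].values
    x = lon - config.lon_extent[0]  # offshore distance, degrees
    depth_profile = np.empty_like(x)
    shelf = x <= SHELF_WIDTH_DEG
    depth_profile[shelf] = 200.0 * x[shelf] / SHELF_WIDTH_DEG
    slope = (x > SHELF_WIDTH_DEG) & (x <= SHELF_WIDTH_DEG + SLOPE_WIDTH_DEG)
    depth_profile[slope] = 200.0 + 1800.0 * (
        (x[slope] - SHELF_WIDTH_DEG) / SLOPE_WIDTH_DEG
    ) ** 1.2
    deep = x > SHELF_WIDTH_DEG + SLOPE_WIDTH_DEG
    span = (config.lon_extent[1] - config.lon_extent[0]) - (
        SHELF_WIDTH_DEG + SLOPE_WIDTH_DEG
    )
    depth_profile[deep] = 2000.0 + (MAX_DEPTH_M - 2000.0) * (
        (x[deep] - SHELF_WIDTH_DEG - SLOPE_WIDTH_DEG) / span
    ) ** 0.8
    # mild along-shore modulation; keeps every row monotone offshore
    mod = 1.0 + 0.08 * np.sin(2 * np.pi * lat / 35.0)
    depth = np.maximum(mod[:, None] * depth_profile[None, :], 1.0)
    ds["depth_m"] = (("lat", "lon"), depth, {"units": "m", "positive": "down"})
    ds["region"] = (("lat", "lon"), gridmod.region_mask(depth))
    return ds


def hypsometry_table(bathy: xr.Dataset, bin_width_m: float = 10.0,
                     max_depth_m: float | None = None) -> pd.DataFrame:
    """Ocean area per depth bin as (depth_m, area_m2), depth at bin centers."""
    if max_depth_m is None:
        max_depth_m = float(bathy["depth_m"].max())
    edges = np.arange(0.0, max_depth_m + 2 * bin_width_m, bin_width_m)
    area = gridmod.hypsometry(bathy["depth_m"].values, bathy["cell_area"].values, edges)
    return pd.DataFrame({"depth_m": 0.5 * (edges[:-1] + edges[1:]), "area_m2": area})


def make_predictors(config: SyntheticWorldConfig, bathy: xr.Dataset) -> xr.Dataset:
    """Static predictor climatologies sharing the bathymetry grid."""
    ds = bathy.copy()
    lat = ds["lat"].values[:, None]
    lon = ds["lon"].values[None, :]
    shape = (ds["lat"].size, ds["lon"].size)

    sst = 28.0 * np.exp(-((lat / 40.0) ** 2)) - 1.0 + 0.5 * np.sin(2 * np.pi * lon / 20.0)
    sss = 33.0 + 2.0 * np.exp(-(((np.abs(lat) - 25.0) / 20.0) ** 2))
    npp = (200.0 + 800.0 * np.exp(-((lat / 45.0) ** 2))) * (
        1.0 + 0.05 * np.sin(2 * np.pi * lon / 20.0)
    )
    poc = 0.15 * npp * (1.0 + 0.2 * np.sin(2 * np.pi * lat / 23.0))
    po4 = 0.1 + 1.9 * (np.abs(lat) / 70.0) ** 1.5 + 0.0 * lon
    o2 = 320.0 - 3.0 * sst + 10.0 * np.sin(2 * np.pi * lat / 17.0)
    depth = ds["depth_m"].values
    hydrate = np.exp(-(((depth - 1000.0) / 600.0) ** 2))
    rng = np.random.default_rng(stage_seed(config.seed, "dms"))
    coarse = rng.normal(1.5, 0.4, (8, 8))
    dms = xr.DataArray(
        coarse,
        coords={
            "lat": np.linspace(lat.min(), lat.max(), 8),
            "lon": np.linspace(lon.min(), lon.max(), 8),
        },
    ).interp(lat=ds["lat"], lon=ds["lon"], kwargs={"fill_value": None}).values

    for name, vals, units in [
        ("sst_C", np.broadcast_to(sst, shape), "degC"),
        ("sss_psu", np.broadcast_to(sss, shape), "psu"),
        ("npp", np.broadcast_to(npp, shape), "mg C m-2 d-1"),
        ("poc_export", np.broadcast_to(poc, shape), "mg C m-2 d-1"),
        ("po4_uM", np.broadcast_to(po4, shape), "uM"),
        ("o2_uM", np.broadcast_to(o2, shape), "uM"),
        ("hydrate", hydrate, "arbitrary"),
        ("dms_nM", dms, "nM"),
    ]:
        ds[name] = (("lat", "lon"), np.ascontiguousarray(vals, dtype=float),
                    {"units": units})
    return ds


def coastal_truth(depth_m, config: SyntheticWorldConfig):
    """Coastal relation: dCH4 = A * z^b [nM]."""
    return config.coastal_amplitude * np.asarray(depth_m, float) ** config.coastal_exponent


def open_ocean_truth(npp, po4, config: SyntheticWorldConfig):
    """Open-ocean relation: dCH4 = (slope*NPP + intercept)/1e3 + c_po4*PO4 [nM]."""
    base = (config.npp_slope * np.asarray(npp, float) + config.npp_intercept) / 1e3
    return base + config.open_po4_coeff * np.asarray(po4, float)


def make_truth_field(config: SyntheticWorldConfig, predictors: xr.Dataset) -> xr.Dataset:
    """dCH4 truth: coastal power law blended into the open-ocean NPP relation.

    The blend ramps linearly over 1500-2500 m so the mapping stage never sees
    a depth discontinuity; an optional polar undersaturation patch produces
    negative dCH4 at high southern latitudes.
    """
    ds = predictors.copy()
    depth = ds["depth_m"].values
    coast = coastal_truth(depth, config)
    open_ = open_ocean_truth(ds["npp"].values, ds["po4_uM"].values, config)
    w = np.clip((depth - 1500.0) / 1000.0, 0.0, 1.0)
    truth = (1.0 - w) * coast + w * open_
    if config.polar_undersaturation:
        lat = ds["lat"].values[:, None]
        patch = config.polar_undersaturation * np.clip(
            (config.polar_lat - lat) / 15.0, 0.0, 1.0
        )
        truth = truth - patch * w  # only where the open-ocean relation dominates
    monthly = np.broadcast_to(truth, (12,) + truth.shape).copy()
    ds["dch4_truth_nM"] = (("month", "lat", "lon"), monthly, {"units": "nM"})
    ds = ds.assign_coords(month=np.arange(1, 13))
    return ds


def mld_climatology(lat, lon, month) -> float:
    """Synthetic mixed-layer depth [m]: deeper in local winter."""
    peak = 2 if lat >= 0 else 8  # month of deepest mixed layer
    return 40.0 + 20.0 * np.cos(2 * np.pi * (month - peak) / 12.0)


# ---------------------------------------------------------------------------
# Atmospheric stations
# ---------------------------------------------------------------------------

STATION_LATS = (-65.0, -30.0, 0.0, 30.0, 65.0)


def _station_pch4(config: SyntheticWorldConfig, lat, year, month):
    t = (year - 1980) + (month - 0.5) / 12.0
    gradient = config.atm_gradient_ppb * (0.5 * np.tanh(np.asarray(lat) / 20.0))
    seasonal = config.atm_seasonal_amp_ppb * np.cos(
        2 * np.pi * (month - 1) / 12.0 + np.pi * (np.asarray(lat) < 0)
    )
    return config.atm_baseline_ppb + config.atm_trend_ppb_yr * t + gradient + seasonal


def make_atm_stations(config: SyntheticWorldConfig,
                      years=range(1980, 2017)) -> pd.DataFrame:
    """Monthly dry-air pCH4 series for a small latitudinal station network."""
    lon_mid = 0.5 * (config.lon_extent[0] + config.lon_extent[1])
    rows = []
    for i, lat in enumerate(STATION_LATS):
        for year in years:
            for month in range(1, 13):
                rows.append(
                    (f"ST{i}", lat, lon_mid, year, month,
                     float(_station_pch4(config, lat, year, month)))
                )
    return pd.DataFrame(
        rows, columns=["station_id", "lat", "lon", "year", "month", "pch4_ppb"]
    )


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def lognormal_noise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise (mu = -sigma^2/2)."""
    if sigma == 0:
        return 1.0 if size is None else np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def sample_observations(truth: xr.Dataset, config: SyntheticWorldConfig,
                        atmosphere: AtmosphericField | None = None) -> pd.DataFrame:
    """Cruise-track observation records of dissolved [CH4].

    Tracks are random walks; half start over the shelf so observation density
    increases toward the coast, mirroring real cruise coverage.  Each record
    carries [CH4] = S(T,S)*pCH4_moist + dCH4_truth * lognormal noise.  A
    configured fraction of records is placed below the mixed layer, and a
    fraction is dated before 1980, to exercise the climatology filters.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "observations"))
    if atmosphere is None:
        atmosphere = AtmosphericField(make_atm_stations(config))
    lat0, lat1 = config.lat_extent
    lon0, lon1 = config.lon_extent
    glat = truth["lat"].values
    glon = truth["lon"].values
    res = truth.attrs["resolution_deg"]
    truth_vals = truth["dch4_truth_nM"].values[0]
    sst = truth["sst_C"].values
    sss = truth["sss_psu"].values

    rows = []
    for track in range(config.n_tracks):
        if track % 2 == 0:  # coastal start
            lon_c = rng.uniform(lon0 + 0.2, lon0 + 6.0)
        else:
            lon_c = rng.uniform(lon0 + 0.2, lon1 - 0.2)
        lat_c = rng.uniform(lat0 + 0.5, lat1 - 0.5)
        if rng.random() < config.out_of_window_fraction:
            year = int(rng.integers(1975, 1980))
        else:
            year = int(rng.integers(1980, 2017))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        date = pd.Timestamp(year=year, month=month, day=day)
        for _ in range(config.obs_per_track):
            lat_c = float(np.clip(lat_c + rng.normal(0, 0.7), lat0 + 0.01, lat1 - 0.01))
            lon_c = float(np.clip(lon_c + rng.normal(0, 0.7), lon0 + 0.01, lon1 - 0.01))
            i = min(int((lat_c - lat0) / res), glat.size - 1)
            j = min(int((lon_c - lon0) / res), glon.size - 1)
            t_obs = float(sst[i, j] + rng.normal(0, 0.2))
            s_obs = float(sss[i, j] + rng.normal(0, 0.1))
            mld = mld_climatology(lat_c, lon_c, month)
            if rng.random() < config.below_mld_fraction:
                depth = float(mld + rng.uniform(5.0, 40.0))
            else:
                depth = float(rng.uniform(1.0, 0.8 * mld))
            noise = float(lognormal_noise(rng, config.noise_sigma, None))
            eq = solubility(t_obs, s_obs) * atmosphere.moist_pch4(
                lat_c, lon_c, year if year >= 1980 else 1980, month, t_obs, s_obs
            )
            ch4 = float(eq + truth_vals[i, j] * noise)
            rows.append((lat_c, lon_c, date.date().isoformat(), depth,
                         t_obs, s_obs, max(ch4, 0.0)))
    return pd.DataFrame(
        rows,
        columns=["lat", "lon", "date", "depth_m", "temperature_C",
                 "salinity_psu", "ch4_nM"],
    )


def sample_coastal_observations(n: int, config: SyntheticWorldConfig,
                                seed: int | None = None) -> pd.DataFrame:
    """Direct draws from the coastal depth relation with default noise.

    Depths are log-uniform over 10-2000 m; dCH4 = A z^b times unit-mean
    lognormal noise.  Used for the observe->bin->fit parameter-recovery path.
    """
    rng = np.random.default_rng(
        stage_seed(config.seed, "coastal-obs") if seed is None else seed
    )
    depth = 10.0 ** rng.uniform(1.0, np.log10(2000.0), n)
    dch4 = coastal_truth(depth, config) * lognormal_noise(rng, config.noise_sigma, n)
    return pd.DataFrame({"depth_m": depth, "dch4_nM": dch4})


def sample_open_ocean_observations(n: int, config: SyntheticWorldConfig,
                                   seed: int | None = None) -> pd.DataFrame:
    """Direct draws from the open-ocean NPP relation with default noise."""
    rng = np.random.default_rng(
        stage_seed(config.seed, "open-obs") if seed is None else seed
    )
    npp = rng.uniform(200.0, 1000.0, n)
    po4 = rng.uniform(0.1, 2.0, n)
    dch4 = open_ocean_truth(npp, po4, config) * lognormal_noise(
        rng, config.noise_sigma, n
    )
    return pd.DataFrame({"npp": npp, "po4_uM": po4, "dch4_nM": dch4})


# ---------------------------------------------------------------------------
# Wind and ice products
# ---------------------------------------------------------------------------

def make_wind_ice_products(config: SyntheticWorldConfig,
                           grid: xr.Dataset) -> tuple[xr.DataArray, xr.DataArray]:
    """Daily zonal wind products and monthly sea-ice fraction products.

    Winds are zonal profiles (product, dayofyear, lat): a shared base field
    with smooth per-product perturbations of configurable scale.  Ice products
    place fractional cover poleward of the configured latitude threshold with
    a seasonal cycle and small inter-product edge shifts.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "wind-ice"))
    lat = grid["lat"].values
    doy = np.arange(1, 366)
    base = (
        4.0
        + 5.0 * np.exp(-(((np.abs(lat) - 45.0) / 18.0) ** 2))[None, :]
        + 1.0 * np.sin(2 * np.pi * doy / 365.0)[:, None]
        * np.sign(lat + 1e-9)[None, :]
    )
    winds = np.empty((config.n_wind_products, doy.size, lat.size))
    for p in range(config.n_wind_products):
        phase_t = rng.uniform(0, 2 * np.pi)
        phase_y = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        pert = amp * np.sin(2 * np.pi * doy / 365.0 + phase_t)[:, None] * np.sin(
            np.pi * lat / (lat.max() - lat.min()) + phase_y
        )[None, :]
        winds[p] = np.maximum(base * (1.0 + config.wind_perturbation_scale * pert), 0.0)
    wind_da = xr.DataArray(
        winds,
        dims=("product", "dayofyear", "lat"),
        coords={"product": np.arange(1, config.n_wind_products + 1),
                "dayofyear": doy, "lat": lat},
        attrs={"units": "m s-1"},
    )

    months = np.arange(1, 13)
    nlat, nlon = grid["lat"].size, grid["lon"].size
    ices = np.zeros((config.n_ice_products, 12, nlat, nlon))
    for p in range(config.n_ice_products):
        edge_shift = rng.uniform(-1.0, 1.0)
        for mi, m in enumerate(months):
            for hemi in (-1, 1):
                peak = 2 if hemi > 0 else 8  # late-winter maximum
                edge = config.ice_lat_threshold + edge_shift - 4.0 * np.cos(
                    2 * np.pi * (m - peak) / 12.0
                )
                frac = np.clip((hemi * lat - edge) / 8.0, 0.0, 1.0)
                ices[p, mi] += np.broadcast_to(frac[:, None], (nlat, nlon))
    ices = np.clip(ices, 0.0, 1.0)
    ice_da = xr.DataArray(
        ices,
        dims=("product", "month", "lat", "lon"),
        coords={"product": np.arange(1, config.n_ice_products + 1),
                "month": months, "lat": lat, "lon": grid["lon"].values},
        attrs={"units": "fraction"},
    )
    return wind_da, ice_da


# ---------------------------------------------------------------------------
# Bubble spectrum
# ---------------------------------------------------------------------------

def make_bubble_spectrum(config: SyntheticWorldConfig) -> pd.DataFrame:
    """Discrete volume-weighted bubble size distribution on 1-10 mm.

    Parametric stand-in for observed seep spectra: lognormal volume weights
    centred at the configured mean diameter, discretized in 0.5 mm bins.
    >= 99% of volume lies in 2-8 mm and the volume-weighted mean is ~4 mm.
    """
    edges = np.arange(1.0, 10.0 + 0.5, 0.5)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = np.log(config.bubble_mean_diameter_mm)
    sig = config.bubble_sigma_ln
    w = np.exp(-((np.log(centers) - mu) ** 2) / (2 * sig**2)) / centers
    w = w / w.sum()
    return pd.DataFrame({"diameter_mm": centers, "volume_fraction": w})


# ---------------------------------------------------------------------------
# World bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    fields: xr.Dataset                 # bathymetry + predictors + dch4 truth
    observations: pd.DataFrame
    stations: pd.DataFrame
    atmosphere: AtmosphericField
    winds: xr.DataArray
    ices: xr.DataArray
    bubble_spectrum: pd.DataFrame
    mld = staticmethod(mld_climatology)


def make_world(config: SyntheticWorldConfig | None = None) -> SyntheticWorld:
    """Generate the full synthetic world under the config's seed."""
    config = config or SyntheticWorldConfig()
    grid = make_grid(config)
    bathy = make_bathymetry(config, grid)
    predictors = make_predictors(config, bathy)
    fields = make_truth_field(config, predictors)
    stations = make_atm_stations(config)
    atmosphere = AtmosphericField(stations)
    obs = sample_observations(fields, config, atmosphere)
    winds, ices = make_wind_ice_products(config, grid)
    spectrum = make_bubble_spectrum(config)
    return SyntheticWorld(config, fields, obs, stations, atmosphere,
                          winds, ices, spectrum)
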