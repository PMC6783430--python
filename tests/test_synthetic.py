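"""Synthetic-world generator: grids, bathymetry, truth relations, products."""

import numpy as np
import pandas as pd
import pytest

from ocean_ch4 import grid as gridmod
from ocean_ch4.constants import EARTH_RADIUS_M
from ocean_ch4.synthetic import (STATION_LATS, SyntheticWorldConfig,
                                 make_atm_stations, make_bathymetry,
                                 make_bubble_spectrum, make_grid,
                                 make_predictors, make_truth_field,
                                 make_wind_ice_products, make_world,
                                 mld_climatology, sample_coastal_observations,
                                 sample_observations)


class TestGrid:
    def test_equal_latitude_cells_have_equal_area(self):
        g = gridmod.make_grid(2.0, (-40, 40), (0, 40))
        area = g["cell_area"].values
        lat = g["lat"].values
        i = np.argmin(np.abs(lat - 31.0))
        j = np.argmin(np.abs(lat + 31.0))
        assert lat[i] == -lat[j]
        assert area[i, 0] == pytest.approx(area[j, 0], rel=1e-12)

    def test_full_sphere_area_sums_to_4_pi_r2(self):
        g = gridmod.make_grid(2.0, (-90, 90), (-180, 180))
        total = g["cell_area"].values.sum()
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_M**2, rel=1e-3)

    def test_cosine_latitude_area_ratio(self):
        g = gridmod.make_grid(0.5, (-70, 70), (0, 40))
        lat = g["lat"].values
        a60 = g["cell_area"].values[np.argmin(np.abs(lat - 60.25)), 0]
        a0 = g["cell_area"].values[np.argmin(np.abs(lat - 0.25)), 0]
        assert a60 / a0 == pytest.approx(np.cos(np.radians(60.25))
                                         / np.cos(np.radians(0.25)), abs=1e-3)

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            gridmod.make_grid(-1.0, (-40, 40), (0, 40))
        with pytest.raises(ValueError):
            SyntheticWorldConfig(resolution=0.0)

    def test_positive_coastal_exponent_rejected(self):
        with pytest.raises(ValueError):
            SyntheticWorldConfig(coastal_exponent=0.5)


class TestBathymetry:
    def test_coast_shallower_than_basin_interior(self, small_world):
        depth = small_world.fields["depth_m"].values
        assert depth[:, 0].max() < depth[:, -1].min()

    def test_depth_monotone_offshore(self, small_world):
        depth = small_world.fields["depth_m"].values
        assert np.all(np.diff(depth, axis=1) >= 0)

    def test_all_four_region_classes_present(self, small_world):
        regions = small_world.fields["region"].values
        assert set(np.unique(regions)) == {0, 1, 2, 3}

    def test_hypsometry_conserves_total_area(self, small_world):
        from ocean_ch4.synthetic import hypsometry_table

        hyp = hypsometry_table(small_world.fields)
        total = small_world.fields["cell_area"].values.sum()
        assert hyp["area_m2"].sum() == pytest.approx(total, rel=1e-12)


class TestTruthField:
    def test_coastal_power_law_value(self, small_config):
        grid = make_grid(small_config)
        fields = make_truth_field(
            small_config, make_predictors(small_config,
                                          make_bathymetry(small_config, grid)))
        # pick a shallow cell and evaluate A * z^b directly
        depth = fields["depth_m"].values
        truth = fields["dch4_truth_nM"].values[0]
        i, j = np.unravel_index(np.argmin(np.abs(depth - 50.0)), depth.shape)
        assert truth[i, j] == pytest.approx(69.0 * depth[i, j] ** -0.8, rel=1e-9)
        assert 69.0 * 50.0**-0.8 == pytest.approx(3.0, abs=0.05)

    def test_open_ocean_npp_relation(self, small_world):
        fields = small_world.fields
        deep = fields["depth_m"].values > 2600
        npp = fields["npp"].values[deep]
        truth = fields["dch4_truth_nM"].values[0][deep]
        lat = np.broadcast_to(fields["lat"].values[:, None],
                              fields["depth_m"].shape)[deep]
        mid = np.abs(lat) < 40  # away from the polar undersaturation patch
        expected = (0.3 * npp[mid] + 14.0) / 1e3
        np.testing.assert_allclose(truth[mid], expected, rtol=1e-9)
        assert (0.3 * 500 + 14) / 1e3 == pytest.approx(0.164)

    def test_blend_is_continuous_across_isobath(self, small_world):
        truth = small_world.fields["dch4_truth_nM"].values[0]
        jumps = np.abs(np.diff(truth, axis=1))
        assert jumps.max() < 5.0  # no discontinuity order of the coastal peak

    def test_polar_undersaturation_present(self, small_world):
        truth = small_world.fields["dch4_truth_nM"].values[0]
        assert truth.min() < 0

    def test_noiseless_refit_recovers_coefficients(self):
        from ocean_ch4.attribution import powerlaw_fit

        cfg = SyntheticWorldConfig(noise_sigma=0.0)
        obs = sample_coastal_observations(4000, cfg, seed=5)
        fit = powerlaw_fit(obs["dch4_nM"], obs["depth_m"])
        assert fit["exponent"] == pytest.approx(-0.8, abs=1e-3)
        assert fit["amplitude"] == pytest.approx(69.0, rel=0.02)


class TestObservations:
    def test_fixed_seed_reproduces_records(self, small_config, small_world):
        again = sample_observations(small_world.fields, small_config,
                                    small_world.atmosphere)
        pd.testing.assert_frame_equal(small_world.observations, again)

    def test_below_mld_fraction_matches_config(self, small_world):
        obs = small_world.observations
        month = pd.to_datetime(obs["date"]).dt.month
        mld = np.array([mld_climatology(la, lo, m) for la, lo, m in
                        zip(obs["lat"], obs["lon"], month)])
        frac = (obs["depth_m"].to_numpy() > mld).mean()
        n = len(obs)
        tol = 3 * np.sqrt(0.15 * 0.85 / n)
        assert abs(frac - 0.15) < tol

    def test_zero_noise_records_carry_cell_truth(self):
        from ocean_ch4.disequilibrium import solubility

        cfg = SyntheticWorldConfig(resolution=2.0, noise_sigma=0.0,
                                   n_tracks=6, obs_per_track=10,
                                   below_mld_fraction=0.0,
                                   out_of_window_fraction=0.0, seed=3)
        world = make_world(cfg)
        obs = world.observations
        res = cfg.resolution
        truth = world.fields["dch4_truth_nM"].values[0]
        for r in obs.itertuples():
            i = int((r.lat - cfg.lat_extent[0]) / res)
            j = int((r.lon - cfg.lon_extent[0]) / res)
            date = pd.Timestamp(r.date)
            eq = solubility(r.temperature_C, r.salinity_psu) * \
                world.atmosphere.moist_pch4(r.lat, r.lon, date.year, date.month,
                                            r.temperature_C, r.salinity_psu)
            assert r.ch4_nM - eq == pytest.approx(truth[i, j], abs=1e-9)

    def test_observation_density_increases_shoreward(self, small_world):
        from ocean_ch4.grid import bin_indices

        fields = small_world.fields
        obs = small_world.observations
        i, j, ok = bin_indices(obs["lat"].to_numpy(), obs["lon"].to_numpy(),
                               fields)
        region_of_obs = fields["region"].values[i[ok], j[ok]]
        counts = np.bincount(region_of_obs, minlength=4)
        areas = np.bincount(fields["region"].values.ravel(),
                            weights=fields["cell_area"].values.ravel(),
                            minlength=4)
        density = counts / areas
        assert density[0] > density[3]


class TestAtmosphere:
    def test_trend_reproduces_printed_endpoints(self, small_config):
        st = make_atm_stations(small_config)
        start = st[st.year == 1980]["pch4_ppb"].mean()
        end = st[st.year == 2016]["pch4_ppb"].mean()
        assert start == pytest.approx(1650, abs=15)
        assert end == pytest.approx(1850, abs=15)

    def test_trend_disabled_gives_constant_annual_means(self):
        cfg = SyntheticWorldConfig(atm_trend_ppb_yr=0.0)
        st = make_atm_stations(cfg)
        annual = st.groupby("year")["pch4_ppb"].mean()
        assert annual.std() == pytest.approx(0.0, abs=1e-9)

    def test_seasonal_amplitude_recovered_by_harmonic_fit(self, small_config):
        st = make_atm_stations(small_config)
        s = st[(st.station_id == "ST4")]
        detrended = s["pch4_ppb"] - np.polyval(
            np.polyfit(s.year + s.month / 12, s["pch4_ppb"], 1),
            s.year + s.month / 12)
        ang = 2 * np.pi * (s.month - 1) / 12
        x = np.column_stack([np.cos(ang), np.sin(ang)])
        coef, *_ = np.linalg.lstsq(x, detrended, rcond=None)
        amp = np.hypot(*coef)
        assert amp == pytest.approx(small_config.atm_seasonal_amp_ppb, rel=0.05)

    def test_station_network_spans_latitudes(self):
        assert len(STATION_LATS) >= 3
        assert max(STATION_LATS) > 0 > min(STATION_LATS)


class TestWindIceProducts:
    def test_zero_perturbation_collapses_products(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, wind_perturbation_scale=0.0)
        winds, _ = make_wind_ice_products(cfg, make_grid(cfg))
        base = winds.sel(product=1).values
        for p in winds["product"].values[1:]:
            np.testing.assert_allclose(winds.sel(product=p).values, base)

    def test_ice_fraction_bounded_and_zero_at_equator(self, small_world):
        ices = small_world.ices
        assert float(ices.min()) >= 0.0 and float(ices.max()) <= 1.0
        equator = np.abs(ices["lat"].values) < 10
        assert float(ices.values[:, :, equator, :].max()) == 0.0

    def test_winds_non_negative_and_deterministic(self, small_config,
                                                  small_world):
        assert float(small_world.winds.min()) >= 0.0
        winds2, _ = make_wind_ice_products(small_config,
                                           make_grid(small_config))
        np.testing.assert_array_equal(small_world.winds.values, winds2.values)


class TestBubbleSpectrum:
    def test_volume_weights_normalized(self, small_config):
        spec = make_bubble_spectrum(small_config)
        assert spec["volume_fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_volume_concentrated_between_2_and_8_mm(self, small_config):
        spec = make_bubble_spectrum(small_config)
        inside = spec["diameter_mm"].between(2, 8)
        assert spec.loc[inside, "volume_fraction"].sum() >= 0.99

    def test_volume_weighted_mean_diameter_near_4_mm(self, small_config):
        spec = make_bubble_spectrum(small_config)
        mean = (spec["diameter_mm"] * spec["volume_fraction"]).sum()
        assert 3.5 <= mean <= 4.5
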