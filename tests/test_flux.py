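"""Gas transfer, daily flux fields, integration, Monte Carlo, sensitivity."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from ocean_ch4 import constants as c
from ocean_ch4.flux import (GasTransferDraw, TransferAggregates,
                            annual_emissions, daily_flux, find_plateau,
                            gas_transfer_velocity, integrate_annual,
                            k660_cm_hr, k_algorithm_spread, monte_carlo,
                            schmidt_number, variance_partition)
from ocean_ch4.mapping import MapEnsemble


def reference_schmidt(t):
    """Independent transcription of the CH4-in-seawater Sc polynomial."""
    return (2101.2 - 131.54 * t + 4.4931 * t**2 - 0.08676 * t**3
            + 0.00070663 * t**4)


class TestSchmidtNumber:
    @pytest.mark.parametrize("t", [0.0, 10.0, 20.0, 30.0])
    def test_matches_independent_transcription(self, t):
        assert schmidt_number(t) == pytest.approx(reference_schmidt(t),
                                                  rel=1e-12)

    def test_monotone_decreasing_and_positive(self):
        t = np.linspace(0, 30, 61)
        sc = schmidt_number(t)
        assert np.all(np.diff(sc) < 0)
        assert np.all(sc > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            schmidt_number(50.0)


class TestGasTransferVelocity:
    def test_quadratic_algorithms_vanish_at_zero_wind(self):
        for alg in (1, 2, 4):
            assert gas_transfer_velocity(0.0, 660.0, alg) == 0.0

    def test_quadratic_coefficient_unit_conversion(self):
        # 0.251 * 10^2 = 25.1 cm/hr -> m/day
        k = gas_transfer_velocity(10.0, 660.0, 1)
        assert k == pytest.approx(25.1 * 0.24, rel=1e-12)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            gas_transfer_velocity(5.0, 660.0, 9)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            k660_cm_hr(-1.0, 1)

    @pytest.mark.parametrize("u", [5.0, 7.5, 10.0])
    def test_algorithms_diverge_beyond_20_percent(self, u):
        assert k_algorithm_spread(u) > 0.20


def tiny_products(nlat=4, nlon=3, u=8.0, ice=0.0):
    lat = np.linspace(-60, 60, nlat)
    lon = np.linspace(2, 38, nlon)
    winds = xr.DataArray(np.full((1, 365, nlat), u),
                         dims=("product", "dayofyear", "lat"),
                         coords={"product": [1], "dayofyear": np.arange(1, 366),
                                 "lat": lat})
    ices = xr.DataArray(np.full((1, 12, nlat, nlon), ice),
                        dims=("product", "month", "lat", "lon"),
                        coords={"product": [1], "month": np.arange(1, 13),
                                "lat": lat, "lon": lon})
    return winds, ices


class TestDailyFlux:
    def setup_method(self):
        self.sst = np.full((4, 3), 15.0)
        self.dch4 = np.full((12, 4, 3), 2.0)

    def test_full_ice_with_complete_blocking_zeroes_flux(self):
        winds, ices = tiny_products(ice=1.0)
        f = daily_flux(self.dch4, winds, ices, self.sst,
                       GasTransferDraw(1, 1, 1, 1.0), day=100)
        np.testing.assert_allclose(f, 0.0, atol=1e-15)

    def test_zero_disequilibrium_zeroes_flux(self):
        winds, ices = tiny_products()
        f = daily_flux(np.zeros((12, 4, 3)), winds, ices, self.sst,
                       GasTransferDraw(1, 1, 1, 1.0), day=1)
        np.testing.assert_allclose(f, 0.0)

    def test_partial_ice_blocking_arithmetic(self):
        winds, ices = tiny_products(ice=1.0)
        open_winds, open_ices = tiny_products(ice=0.0)
        f_blocked = daily_flux(self.dch4, winds, ices, self.sst,
                               GasTransferDraw(1, 1, 1, 0.9), day=50)
        f_open = daily_flux(self.dch4, open_winds, open_ices, self.sst,
                            GasTransferDraw(1, 1, 1, 0.9), day=50)
        np.testing.assert_allclose(f_blocked, 0.1 * f_open, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        winds, ices = tiny_products()
        with pytest.raises(ValueError):
            daily_flux(self.dch4, winds, ices, np.full((5, 3), 15.0),
                       GasTransferDraw(1, 1, 1, 1.0), day=1)

    def test_negative_disequilibrium_gives_uptake(self):
        winds, ices = tiny_products()
        f = daily_flux(-self.dch4, winds, ices, self.sst,
                       GasTransferDraw(1, 1, 1, 1.0), day=1)
        assert (f < 0).all()


class TestIntegration:
    def test_uniform_flux_unit_conversion(self):
        # 1 mmol m^-2 yr^-1 over area A -> 16.043e-15 * A Tg yr^-1
        area = np.full((2, 2), 1e10)
        region = np.zeros((2, 2), dtype=int)
        daily = [np.full((2, 2), 1.0 / 365.0)] * 365
        out = integrate_annual(daily, area, region)
        expected = 1e-3 * c.CH4_MOLAR_MASS_G * 4e10 * 1e-12
        assert out["global"] == pytest.approx(expected, rel=1e-9)

    def test_regions_partition_global(self, small_world, small_ensemble):
        agg = TransferAggregates(small_world.winds, small_world.ices,
                                 small_world.fields["sst_C"].values)
        a, b = agg.terms(1, 1, 1)
        reg = annual_emissions(small_ensemble.maps[0], a, b, 0.95,
                               small_world.fields["cell_area"].values,
                               small_world.fields["region"].values)
        total = annual_emissions(small_ensemble.maps[0], a, b, 0.95,
                                 small_world.fields["cell_area"].values,
                                 np.zeros_like(small_world.fields["region"].values))
        assert reg.sum() == pytest.approx(total.sum(), rel=1e-12)

    def test_zero_world_integrates_to_zero(self, small_world):
        agg = TransferAggregates(small_world.winds, small_world.ices,
                                 small_world.fields["sst_C"].values)
        a, b = agg.terms(1, 1, 1)
        reg = annual_emissions(np.zeros_like(a), a, b, 0.95,
                               small_world.fields["cell_area"].values,
                               small_world.fields["region"].values)
        assert reg.sum() == 0.0

    def test_aggregate_path_matches_literal_daily_loop(self, small_world,
                                                       small_ensemble):
        w = small_world
        draw = GasTransferDraw(2, 1, 3, 0.93)
        agg = TransferAggregates(w.winds, w.ices, w.fields["sst_C"].values)
        a, b = agg.terms(2, 1, 3)
        fast = annual_emissions(small_ensemble.maps[0], a, b, 0.93,
                                w.fields["cell_area"].values,
                                w.fields["region"].values).sum()
        daily = (daily_flux(small_ensemble.maps[0], w.winds, w.ices,
                            w.fields["sst_C"].values, draw, d)
                 for d in range(1, 366))
        literal = integrate_annual(daily, w.fields["cell_area"].values,
                                   w.fields["region"].values)["global"]
        assert fast == pytest.approx(literal, rel=1e-10)

    def test_flux_linear_in_dch4(self, small_world, small_ensemble):
        w = small_world
        agg = TransferAggregates(w.winds, w.ices, w.fields["sst_C"].values)
        a, b = agg.terms(1, 2, 2)
        one = annual_emissions(small_ensemble.maps[0], a, b, 0.95,
                               w.fields["cell_area"].values,
                               w.fields["region"].values).sum()
        three = annual_emissions(3.0 * small_ensemble.maps[0], a, b, 0.95,
                                 w.fields["cell_area"].values,
                                 w.fields["region"].values).sum()
        # maps are stored float32, so linearity holds to single precision
        assert three == pytest.approx(3.0 * one, rel=1e-6)


class TestMonteCarlo:
    def run_mc(self, world, ensemble, n_draws, seed=1):
        return monte_carlo(ensemble, world.winds, world.ices,
                           world.fields["sst_C"].values,
                           world.fields["cell_area"].values,
                           world.fields["region"].values,
                           n_draws=n_draws, seed=seed)

    def test_single_draw_distribution_degenerate(self, small_world,
                                                 small_ensemble):
        res = self.run_mc(small_world, small_ensemble, 1)
        s = res.summary()
        g = s[s.region == "global"].iloc[0]
        assert g["p10"] == g["p90"] == g["mean"]

    def test_doubling_draws_preserves_mean_within_mc_error(self, small_world,
                                                           small_ensemble):
        r1 = self.run_mc(small_world, small_ensemble, 150, seed=2)
        r2 = self.run_mc(small_world, small_ensemble, 300, seed=3)
        g1, g2 = r1.table["global"], r2.table["global"]
        se = np.hypot(g1.std() / np.sqrt(len(g1)), g2.std() / np.sqrt(len(g2)))
        assert abs(g1.mean() - g2.mean()) < 4 * se

    def test_percentile_band_contains_median(self, small_world,
                                             small_ensemble):
        res = self.run_mc(small_world, small_ensemble, 100)
        s = res.summary()
        assert ((s["p10"] <= s["p50"]) & (s["p50"] <= s["p90"])).all()

    def test_per_family_summaries_available(self, small_world, small_ensemble):
        res = self.run_mc(small_world, small_ensemble, 80)
        for family in ("ann", "rrf"):
            s = res.summary(family=family)
            assert len(s) == 5


class TestVariancePartition:
    def test_single_permutation_zeroes_transfer_variance(self, small_world,
                                                         small_ensemble):
        winds = small_world.winds.sel(product=[1])
        ices = small_world.ices.sel(product=[1])
        agg = TransferAggregates(winds, ices, small_world.fields["sst_C"].values)
        a, b = agg.terms(1, 1, 1)
        vals = [annual_emissions(small_ensemble.mean_map(), a, b, 0.95,
                                 small_world.fields["cell_area"].values,
                                 small_world.fields["region"].values).sum()
                for _ in range(3)]
        assert np.var(vals) == 0.0

    def test_identical_maps_zero_dch4_variance(self, small_world,
                                               small_ensemble):
        clone = MapEnsemble(members=[],
                            maps=np.repeat(small_ensemble.maps[:1], 4, axis=0),
                            families=np.array(["ann"] * 4),
                            lat=small_ensemble.lat, lon=small_ensemble.lon)
        out = variance_partition(clone, small_world.winds, small_world.ices,
                                 small_world.fields["sst_C"].values,
                                 small_world.fields["cell_area"].values,
                                 small_world.fields["region"].values)
        assert out["dch4_variance"] == pytest.approx(0.0, abs=1e-20)


class TestResolutionSweep:
    def test_plateau_detection_on_constructed_table(self):
        res = [2.0, 1.0, 0.5, 0.25]
        flux = [3.0, 2.0, 1.55, 1.5]
        assert find_plateau(res, flux, tolerance=0.1) == 0.5
        assert find_plateau(res, flux, tolerance=1.0) == 2.0

    def test_same_seed_same_resolution_reproducible(self, small_world):
        from ocean_ch4.disequilibrium import delta_ch4, mixed_layer_filter
        from ocean_ch4.flux import resolution_sweep
        from ocean_ch4.synthetic import mld_climatology

        kept = mixed_layer_filter(small_world.observations, mld_climatology)
        rec = delta_ch4(kept, small_world.atmosphere)
        a = resolution_sweep(rec, small_world.config, [4.0], n_members=2,
                             n_draws=20, seed=9)
        b = resolution_sweep(rec, small_world.config, [4.0], n_members=2,
                             n_draws=20, seed=9)
        pd.testing.assert_frame_equal(a, b)
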