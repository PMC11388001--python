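"""Synthetic generators: structure, determinism, scenario surrogates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

import urbanheat as uh


class TestStationSeries:
    def test_same_seed_identical_series(self):
        a = uh.gen_station_series(n_years=3, seed=5)
        b = uh.gen_station_series(n_years=3, seed=5)
        assert a.data.equals(b.data)

    def test_different_seed_differs(self):
        a = uh.gen_station_series(n_years=1, seed=5)
        b = uh.gen_station_series(n_years=1, seed=6)
        assert not a.data.equals(b.data)

    def test_background_mean_passes_through_to_threshold(self):
        s = uh.gen_station_series(
            n_years=10, base_climate={"mean_tmax": 25.6, "seasonal_amp": 0.0,
                                      "noise_sd": 0.2}, seed=1)
        thr = uh.climatological_threshold([s])
        assert thr == pytest.approx(25.6, abs=0.05)

    def test_overlapping_embedded_events_rejected(self):
        with pytest.raises(ValueError):
            uh.gen_station_series(
                n_years=1,
                embedded_events=[("1990-07-01", 6, 34.0), ("1990-07-04", 6, 35.0)],
                seed=0)

    def test_embedded_run_detected_with_exact_duration(self):
        s = uh.gen_station_series(
            n_years=1, base_climate={"mean_tmax": 30.0, "seasonal_amp": 0.0,
                                     "noise_sd": 0.3},
            embedded_events=[("1990-08-01", 6, 34.0)], seed=2)
        events = uh.detect_events(s.data, 32.1)
        assert len(events) == 1 and events[0].duration == 6

    def test_csv_round_trip(self, tmp_path):
        s = uh.gen_station_series(n_years=1, seed=3)
        p = tmp_path / "station.csv"
        s.to_csv(p)
        back = uh.StationSeries.from_csv(p)
        assert back.station_id == s.station_id
        assert np.allclose(back.data.to_numpy(), s.data.to_numpy())


class TestUrbanGrid:
    def test_fractions_valid_and_complementary(self, small_grid):
        t = small_grid.table
        for col in ("svi", "street_fraction", "roof_fraction", "tree_cover"):
            assert t[col].between(0, 1).all()
        assert np.allclose(t["street_fraction"] + t["roof_fraction"], 1.0,
                           atol=1e-12)

    def test_houston_pattern_street_rises_tc_falls_with_svi(self):
        g = uh.gen_urban_grid(5000, seed=4)
        rho_street = spearmanr(g.svi, g.street_fraction).statistic
        rho_tc = spearmanr(g.svi, g.tree_cover).statistic
        assert rho_street > 0.3
        assert rho_tc < -0.3
        assert g.street_fraction[g.svi > 0.9].mean() == pytest.approx(0.40, abs=0.02)
        assert g.street_fraction[g.svi < 0.1].mean() < 0.30

    def test_zero_slope_decorrelates_street_from_svi(self):
        g = uh.gen_urban_grid(10_000, svi_street_slope=0.0, seed=5)
        r = pearsonr(g.svi, g.street_fraction).statistic
        assert abs(r) < 0.1

    def test_single_cell_grid_is_valid(self):
        g = uh.gen_urban_grid(1, seed=6)
        assert len(g) == 1
        assert g.street_fraction[0] + g.roof_fraction[0] == pytest.approx(1.0)

    def test_equity_target_adds_more_canopy_where_vulnerable(self):
        g = uh.gen_urban_grid(5000, seed=7)
        hi = g.tc_added_target[g.svi > 0.8].mean()
        lo = g.tc_added_target[g.svi < 0.2].mean()
        assert hi > lo

    def test_determinism_and_csv_round_trip(self, tmp_path):
        a = uh.gen_urban_grid(50, seed=8)
        b = uh.gen_urban_grid(50, seed=8)
        pd.testing.assert_frame_equal(a.table, b.table)
        p = tmp_path / "grid.csv"
        a.to_csv(p)
        back = uh.UrbanGrid.from_csv(p)
        assert np.allclose(back.svi, a.svi)


class TestMetForcing:
    def test_same_seed_bit_identical(self, small_grid):
        a = uh.gen_met_forcing(small_grid, n_days=1, seed=9)
        b = uh.gen_met_forcing(small_grid, n_days=1, seed=9)
        assert a.ds.identical(b.ds)

    def test_zero_amplitude_gives_constant_fields(self, small_grid):
        flat = {"t2_amp": 0.0, "rh2_amp": 0.0, "ws_amp": 0.0, "s0": 0.0,
                "noise_sd": 0.0, "cell_sd": 0.0, "mrt_night_offset": 0.0}
        m = uh.gen_met_forcing(small_grid, n_days=2, diurnal_params=flat, seed=0)
        for var in ("t2", "rh2", "ws10", "mrt", "sw_down"):
            assert np.ptp(m.ds[var].values) == 0.0

    def test_heatwave_preset_every_cell_tops_35_1(self, heatwave_met):
        t2 = heatwave_met.ds["t2"].values
        daily_max = t2.reshape(2, 24, -1).max(axis=1)
        assert daily_max.min() > 35.1

    def test_shortwave_zero_at_night_positive_at_noon(self, heatwave_met):
        sw = heatwave_met.ds["sw_down"].values
        hod = heatwave_met.times.hour.to_numpy()
        assert np.all(sw[(hod < 6) | (hod > 18)] == 0.0)
        assert np.all(sw[hod == 12] > 0.0)

    def test_humidity_bounds_respected(self, heatwave_met):
        rh = heatwave_met.ds["rh2"].values
        assert rh.min() >= 0.0 and rh.max() <= 100.0

    def test_netcdf_round_trip(self, small_grid, tmp_path):
        m = uh.gen_met_forcing(small_grid, n_days=1, seed=10)
        p = tmp_path / "met.nc"
        m.to_netcdf(p)
        back = uh.MetField.from_netcdf(p)
        for var in ("t2", "rh2", "ws10", "mrt", "sw_down"):
            assert np.allclose(back.ds[var].values, m.ds[var].values)

    def test_csv_round_trip(self, small_grid, tmp_path):
        m = uh.gen_met_forcing(small_grid, n_days=1, seed=10)
        p = tmp_path / "met.csv"
        m.to_csv(p)
        back = uh.MetField.from_csv(p)
        assert np.allclose(back.ds["t2"].values, m.ds["t2"].values)


class TestScenarioSpec:
    @pytest.mark.parametrize("strategy, intensity, attr, value", [
        ("cool_roof", "low", "roof_albedo", 0.55),
        ("cool_roof", "high", "roof_albedo", 0.70),
        ("green_roof", "low", "green_roof_coverage", 0.30),
        ("green_roof", "high", "green_roof_coverage", 0.80),
        ("urban_trees", "low", "tc_target_multiplier", 0.5),
        ("urban_trees", "high", "tc_target_multiplier", 1.0),
    ])
    def test_programme_intensities(self, strategy, intensity, attr, value):
        assert getattr(uh.ScenarioSpec.named(strategy, intensity), attr) == value

    def test_control_is_neutral(self):
        c = uh.ScenarioSpec.named("control")
        assert c.roof_albedo == pytest.approx(0.19)
        assert c.green_roof_coverage == 0.0
        assert c.tc_target_multiplier == 0.0

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            uh.ScenarioSpec.named("solar_panels", "high")

    def test_suite_has_seven_experiments(self):
        names = [s.name for s in uh.ScenarioSpec.experiment_suite()]
        assert len(names) == 7 and len(set(names)) == 7
        assert "control" in names


class TestScenarioSurrogate:
    def test_control_returns_input_exactly(self, small_grid, heatwave_met):
        out = uh.apply_scenario_surrogate(
            heatwave_met, small_grid, uh.ScenarioSpec.named("control"))
        assert out.ds.identical(heatwave_met.ds)

    def test_trees_with_no_added_canopy_change_nothing(self, heatwave_met,
                                                       small_grid):
        grid = uh.UrbanGrid(small_grid.table.assign(tc_added_target=0.0))
        out = uh.apply_scenario_surrogate(
            heatwave_met, grid, uh.ScenarioSpec.named("urban_trees", "high"))
        assert np.allclose(out.ds["mrt"].values, heatwave_met.ds["mrt"].values)

    def test_cool_roof_cools_more_where_roofs_dominate(self):
        table = pd.DataFrame({
            "cell_id": [0, 1], "svi": [0.5, 0.5],
            "street_fraction": [0.3, 0.4], "roof_fraction": [0.7, 0.6],
            "tree_cover": [0.1, 0.1], "tc_added_target": [0.0, 0.0],
            "is_urban": [True, True],
        })
        grid = uh.UrbanGrid(table)
        met = uh.gen_met_forcing(grid, n_days=1,
                                 diurnal_params={"noise_sd": 0.0, "cell_sd": 0.0},
                                 seed=0)
        out = uh.apply_scenario_surrogate(
            met, grid, uh.ScenarioSpec.named("cool_roof", "high"))
        dt2 = out.ds["t2"].values - met.ds["t2"].values
        noon = met.times.hour.to_numpy() == 12
        assert dt2[noon, 0] < dt2[noon, 1] < 0

    def test_cool_roof_moistens_while_cooling(self, small_grid, heatwave_met):
        out = uh.apply_scenario_surrogate(
            heatwave_met, small_grid, uh.ScenarioSpec.named("cool_roof", "high"))
        day = heatwave_met.ds["sw_down"].values > 0
        assert (out.ds["t2"].values - heatwave_met.ds["t2"].values)[day].mean() < 0
        assert (out.ds["rh2"].values - heatwave_met.ds["rh2"].values)[day].mean() > 0

    def test_green_roof_warms_only_at_night(self, small_grid, heatwave_met):
        out = uh.apply_scenario_surrogate(
            heatwave_met, small_grid, uh.ScenarioSpec.named("green_roof", "high"))
        dt2 = out.ds["t2"].values - heatwave_met.ds["t2"].values
        night = heatwave_met.ds["sw_down"].values == 0
        assert dt2[night].min() > 0
        assert dt2[~night].mean() < 0

    def test_trees_touch_only_radiant_temperature(self, small_grid, heatwave_met):
        out = uh.apply_scenario_surrogate(
            heatwave_met, small_grid, uh.ScenarioSpec.named("urban_trees", "high"))
        for var in ("t2", "rh2", "ws10", "sw_down"):
            assert np.array_equal(out.ds[var].values, heatwave_met.ds[var].values)
        day = heatwave_met.ds["sw_down"].values > 0
        dmrt = out.ds["mrt"].values - heatwave_met.ds["mrt"].values
        assert dmrt[day].mean() < 0
        assert np.all(dmrt[~day] == 0.0)

    def test_half_planting_gives_half_the_radiant_cooling(self, small_grid,
                                                          heatwave_met):
        hi = uh.apply_scenario_surrogate(
            heatwave_met, small_grid, uh.ScenarioSpec.named("urban_trees", "high"))
        lo = uh.apply_scenario_surrogate(
            heatwave_met, small_grid, uh.ScenarioSpec.named("urban_trees", "low"))
        d_hi = hi.ds["mrt"].values - heatwave_met.ds["mrt"].values
        d_lo = lo.ds["mrt"].values - heatwave_met.ds["mrt"].values
        assert np.allclose(d_lo, 0.5 * d_hi, atol=1e-9)
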