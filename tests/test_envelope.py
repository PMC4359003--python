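"""Envelope model: layer means, monthly binning, classification, frequencies, rasters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shipworm as sw
from shipworm.envelope import (
    BOTTOM,
    SURFACE,
    EnvelopeThresholds,
    read_esri_ascii,
    read_geotiff,
)
from shipworm.synthetic import ConfigurationError, FormatError


def _hand_fields(depths, values_by_bin, depth_edges=(0.0, 9.0, 25.0)):
    """Tiny single-time HydroFieldSet with per-bin constant values."""
    g = sw.make_grid(2, 2, list(depth_edges), (10.0, 12.0, 54.0, 56.0))
    b = sw.Bathymetry(np.asarray(depths, dtype=float))
    nz = g.n_depth
    arr = np.empty((1, nz, 2, 2))
    for k in range(nz):
        arr[0, k] = values_by_bin[k]
    arr[0][:, b.land_mask] = np.nan
    times = np.array(["2000-06-15"], dtype="datetime64[s]")
    fields = sw.HydroFieldSet(g, times, arr.copy(), np.abs(arr.copy()), np.abs(arr.copy()))
    return g, b, fields


class TestExtractLayer:
    def test_uniform_column_surface_equals_bottom(self):
        g, b, f = _hand_fields([[25.0, 25.0], [25.0, 25.0]], [7.0, 7.0])
        surf = sw.extract_layer(f, b, SURFACE)
        bot = sw.extract_layer(f, b, BOTTOM)
        np.testing.assert_allclose(surf.temperature, bot.temperature)
        np.testing.assert_allclose(surf.temperature[0], 7.0)

    def test_single_bin_layers(self):
        # bins [0,9] and [9,25] with T = 12 and 6; local depth 25
        g, b, f = _hand_fields([[25.0, 25.0], [25.0, 25.0]], [12.0, 6.0])
        surf = sw.extract_layer(f, b, SURFACE)
        bot = sw.extract_layer(f, b, BOTTOM)
        np.testing.assert_allclose(surf.temperature[0], 12.0)
        np.testing.assert_allclose(bot.temperature[0], 6.0)

    def test_bottom_layer_thickness_weighting_across_bins(self):
        # local depth 10 m: bottom layer spans 8-10 m -> 1 m in each bin
        g, b, f = _hand_fields([[10.0, 10.0], [10.0, 10.0]], [12.0, 6.0])
        bot = sw.extract_layer(f, b, BOTTOM)
        np.testing.assert_allclose(bot.temperature[0], 0.5 * 12.0 + 0.5 * 6.0)

    def test_shallow_water_layers_overlap(self):
        # local depth 6 m (< 9 m): both layers draw on the same single bin
        g, b, f = _hand_fields([[6.0, 6.0], [6.0, 6.0]], [14.0, 6.0])
        surf = sw.extract_layer(f, b, SURFACE)
        bot = sw.extract_layer(f, b, BOTTOM)
        np.testing.assert_allclose(surf.temperature[0], 14.0)
        np.testing.assert_allclose(bot.temperature[0], 14.0)

    def test_land_cells_are_nan(self):
        g, b, f = _hand_fields([[10.0, 0.0], [10.0, 10.0]], [12.0, 6.0])
        surf = sw.extract_layer(f, b, SURFACE)
        assert np.isnan(surf.temperature[0, 0, 1])


class TestMonthlyBin:
    def test_constant_field(self):
        g, b, f = _hand_fields([[25.0, 25.0]] * 2, [5.0, 5.0])
        state = sw.monthly_bin(sw.extract_layer(f, b, SURFACE))
        assert state.months == [(2000, 6)]
        np.testing.assert_allclose(state.temperature[0], 5.0)

    def test_daily_values_average(self, grid, bathy, scenario, hydro_year):
        lay = sw.extract_layer(hydro_year, bathy, SURFACE)
        state = sw.monthly_bin(lay)
        # independent closed-form mean of the SST sinusoid over June 2000 days
        june = [m == (2000, 6) for m in state.months].index(True)
        doy = np.arange(153, 183)  # June 2000 day-of-year (leap year)
        expected = np.mean(
            scenario.sst_mean
            + scenario.sst_amplitude
            * np.cos(2 * np.pi * (doy - scenario.sst_peak_day) / 365.2425)
        )
        cell = np.nanmax(state.temperature[june])
        assert cell == pytest.approx(expected, abs=1e-9)

    def test_twelve_months_present(self, hydro_year, bathy):
        state = sw.monthly_bin(sw.extract_layer(hydro_year, bathy, SURFACE))
        assert [m for (_y, m) in state.months] == list(range(1, 13))


class TestClassify:
    @pytest.mark.parametrize(
        "t, s, o, layer, expected",
        [
            (12.0, 8.0, 4.0, SURFACE, True),  # inclusive boundaries
            (11.5, 30.0, 9.0, SURFACE, False),  # below metamorphosis threshold
            (11.5, 30.0, 9.0, BOTTOM, True),  # reproduction-only column passes
            (20.0, 7.9, 9.0, SURFACE, False),  # salinity fails both columns
            (20.0, 7.9, 9.0, BOTTOM, False),
            (20.0, 30.0, 3.9, SURFACE, False),  # oxygen fails
        ],
    )
    def test_threshold_columns(self, t, s, o, layer, expected):
        g = sw.make_grid(2, 2, [0, 9], (10, 12, 54, 56))
        state = sw.envelope.MonthlyLayerState(
            g,
            [(2000, 6)],
            layer,
            np.full((1, 2, 2), t),
            np.full((1, 2, 2), s),
            np.full((1, 2, 2), o),
        )
        mask = sw.classify(state, EnvelopeThresholds())
        assert bool(mask.favourable[0, 0, 0]) is expected

    def test_ignore_oxygen_flag(self):
        g = sw.make_grid(2, 2, [0, 9], (10, 12, 54, 56))
        state = sw.envelope.MonthlyLayerState(
            g, [(2000, 6)], SURFACE,
            np.full((1, 2, 2), 15.0), np.full((1, 2, 2), 10.0), np.full((1, 2, 2), 1.0),
        )
        assert not sw.classify(state, EnvelopeThresholds()).favourable.any()
        assert sw.classify(state, EnvelopeThresholds(), ignore_oxygen=True).favourable.all()


@pytest.fixture(scope="module")
def year_mask(small_state):
    g, b, state = small_state
    return g, b, sw.classify(state, EnvelopeThresholds())


class TestFrequencies:
    def test_always_favourable_is_100(self, year_mask):
        g, b, mask = year_mask
        forced = sw.FavourabilityMask(
            g, mask.months, mask.layer, mask.defined.copy(), mask.defined.copy()
        )
        f = sw.frequency_overall(forced, (2000, 2000))
        sea = np.isfinite(f.percent_favourable)
        assert np.all(f.percent_favourable[sea] == 100.0)

    def test_six_of_twelve_months_is_50(self, year_mask):
        g, b, mask = year_mask
        fav = np.zeros_like(mask.defined)
        fav[:6] = mask.defined[:6]
        half = sw.FavourabilityMask(g, mask.months, mask.layer, fav, mask.defined)
        f = sw.frequency_overall(half, (2000, 2000))
        sea = np.isfinite(f.percent_favourable)
        assert np.all(f.percent_favourable[sea] == 50.0)

    def test_overall_equals_weighted_mean_of_monthly(self, year_mask):
        """Brute-force conservation oracle: overall = defined-month-weighted
        mean of the 12 monthly frequencies."""
        g, b, mask = year_mask
        overall = sw.frequency_overall(mask, (2000, 2000)).percent_favourable
        num = np.zeros_like(overall)
        den = np.zeros_like(overall)
        for month in range(1, 13):
            fm = sw.frequency_by_month(mask, (2000, 2000), month)
            sel = np.array([m == month for (_y, m) in mask.months])
            n_def = mask.defined[sel].sum(axis=0)
            w = np.where(np.isfinite(fm.percent_favourable), fm.percent_favourable, 0.0)
            num += w * n_def
            den += n_def
        with np.errstate(invalid="ignore"):
            recon = num / den
        sea = den > 0
        np.testing.assert_allclose(overall[sea], recon[sea], atol=1e-9)

    def test_monthly_counts_by_brute_force(self, year_mask):
        g, b, mask = year_mask
        fm = sw.frequency_by_month(mask, (2000, 2000), 7)
        k = [m for m in mask.months].index((2000, 7))
        sea = mask.defined[k]
        expected = np.where(mask.favourable[k], 100.0, 0.0)
        np.testing.assert_array_equal(
            fm.percent_favourable[sea], expected[sea]
        )

    def test_month_outside_data_raises(self, year_mask):
        g, b, mask = year_mask
        with pytest.raises(ConfigurationError):
            sw.frequency_by_month(mask, (1990, 1990), 7)

    def test_period_month_single_year_values_binary(self, year_mask):
        g, b, mask = year_mask
        maps = sw.frequency_period_month(mask, [(2000, 2000)], 8)
        vals = maps[0].percent_favourable
        vals = vals[np.isfinite(vals)]
        assert set(np.unique(vals)) <= {0.0, 100.0}

    def test_overlapping_periods_rejected(self, year_mask):
        g, b, mask = year_mask
        with pytest.raises(ConfigurationError):
            sw.frequency_period_month(mask, [(2000, 2000), (2000, 2001)], 8)

    @given(
        dt=st.floats(0, 5),
        ds=st.floats(0, 5),
        do=st.floats(0, 5),
    )
    def test_raising_thresholds_never_increases_frequency(self, small_state, dt, ds, do):
        g, b, state = small_state
        base = sw.frequency_overall(
            sw.classify(state, EnvelopeThresholds()), (2000, 2000)
        ).percent_favourable
        raised = EnvelopeThresholds(
            temp_min_metamorphosis=12.0 + dt,
            temp_min_reproduction=11.0 + dt,
            sal_min=8.0 + ds,
            oxy_min=4.0 + do,
        )
        high = sw.frequency_overall(
            sw.classify(state, raised), (2000, 2000)
        ).percent_favourable
        sea = np.isfinite(base)
        assert np.all(high[sea] <= base[sea] + 1e-12)

    def test_bottom_temperature_column_dominates(self, small_state):
        """Same layer state classified with the reproduction-only column (>=11)
        is favourable at least wherever the metamorphosis column (>=12) is."""
        g, b, state = small_state
        thr = EnvelopeThresholds()
        f_surf = sw.frequency_overall(
            sw.classify(state, thr, layer=SURFACE), (2000, 2000)
        ).percent_favourable
        f_bot = sw.frequency_overall(
            sw.classify(state, thr, layer=BOTTOM), (2000, 2000)
        ).percent_favourable
        sea = np.isfinite(f_surf)
        assert np.all(f_bot[sea] >= f_surf[sea])


class TestRasterExport:
    def _square_map(self):
        g = sw.make_grid(4, 4, [0, 9], (10.0, 12.0, 54.0, 56.0))
        vals = np.arange(16, dtype=float).reshape(4, 4) * 6.0
        vals[0, 0] = np.nan
        return sw.FrequencyMap(g, vals, "overall", SURFACE, (2000, 2000))

    def test_esri_ascii_round_trip(self, tmp_path):
        fmap = self._square_map()
        p = tmp_path / "m.asc"
        sw.export_map(fmap, p, "esri_ascii")
        arr, header = read_esri_ascii(p)
        np.testing.assert_allclose(arr, fmap.percent_favourable, atol=1e-6)
        assert header["NCOLS"] == 4 and header["CELLSIZE"] == pytest.approx(0.5)

    def test_esri_ascii_rejects_anisotropic_cells(self, tmp_path, grid):
        fmap = sw.FrequencyMap(
            grid, np.zeros((grid.n_lat, grid.n_lon)), "overall", SURFACE, (2000, 2000)
        )
        with pytest.raises(FormatError):
            sw.export_map(fmap, tmp_path / "m.asc", "esri_ascii")

    def test_geotiff_round_trip_independent_reader(self, tmp_path):
        fmap = self._square_map()
        p = tmp_path / "m.tif"
        sw.export_map(fmap, p, "geotiff")
        arr, tags = read_geotiff(p)
        np.testing.assert_allclose(arr, fmap.percent_favourable, atol=1e-4)
        assert tags["pixel_scale"][:2] == (0.5, 0.5)
        # tiepoint anchors the north-west corner of the grid
        assert tags["tiepoint"][3:5] == (10.0, 56.0)

    def test_all_land_map_is_all_nodata(self, tmp_path):
        g = sw.make_grid(4, 4, [0, 9], (10.0, 12.0, 54.0, 56.0))
        fmap = sw.FrequencyMap(g, np.full((4, 4), np.nan), "overall", SURFACE, (2000, 2000))
        p = tmp_path / "land.asc"
        sw.export_map(fmap, p, "esri_ascii")
        arr, _ = read_esri_ascii(p)
        assert np.isnan(arr).all()


class TestLongTable:
    def test_table_counts_match_mask(self, year_mask):
        g, b, mask = year_mask
        table = sw.envelope.mask_to_table(mask)
        assert len(table) == int(mask.defined.sum())
        assert table["favourable"].sum() == int(mask.favourable.sum())
        assert set(table["layer"]) == {"surface"}
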