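"""Covariate derivation: gear geometry, light condition, depth, design matrix."""
import numpy as np
import pandas as pd
import pytest

from bycatch import covariates as cov
from conftest import make_effort_frame


class TestHeadlineDepth:
    @pytest.mark.parametrize("g,h,expected", [(100, 60, 40), (210, 10, 200)])
    def test_subtraction(self, g, h, expected):
        assert cov.derive_headline_depth(g, h) == expected

    def test_headline_above_surface_is_error(self):
        with pytest.raises(cov.InvalidGearError):
            cov.derive_headline_depth(50, 60)

    def test_array_input_flags_invalid_rows_as_nan(self):
        out = cov.derive_headline_depth(np.array([100.0, 50.0]),
                                        np.array([60.0, 60.0]))
        assert out[0] == 40.0 and np.isnan(out[1])


class TestDepthFactor:
    @pytest.mark.parametrize("depth,label", [
        (100, "shallow"), (210, "deep"), (1000, "deep"),
    ])
    def test_threshold_is_strictly_less_than_210(self, depth, label):
        assert cov.classify_depth_factor(depth) == label


class TestDepthGrid:
    def _plane_grid(self):
        # depth(lat, lon) = 1000 + 100*(lat + 40) + 10*(lon - 171), cell centres
        cell = 0.1
        lats = -40.0 + cell * (np.arange(20) + 0.5)
        lons = 171.0 + cell * (np.arange(20) + 0.5)
        vals = 1000 + 100 * (lats[::-1, None] + 40) + 10 * (lons[None, :] - 171)
        return cov.DepthGrid(values=vals, xllcorner=171.0, yllcorner=-40.0,
                             cellsize=cell)

    def test_cell_centre_matches_analytic_plane(self):
        g = self._plane_grid()
        lat, lon = -39.25, 171.85
        expect = 1000 + 100 * (lat + 40) + 10 * (lon - 171)
        assert abs(g.at(lat, lon) - expect) < 1e-9

    def test_minimum_of_start_and_end(self):
        g = self._plane_grid()
        tows = make_effort_frame(1, start_lat=-39.95, start_lon=171.05,
                                 end_lat=-39.05, end_lon=171.95)
        d = cov.lookup_bottom_depth(tows, g)
        start_d = g.at(-39.95, 171.05)
        assert d[0] == pytest.approx(start_d)

    def test_identical_positions_give_that_cell(self):
        g = self._plane_grid()
        tows = make_effort_frame(1, start_lat=-39.55, start_lon=171.55,
                                 end_lat=-39.55, end_lon=171.55)
        assert cov.lookup_bottom_depth(tows, g)[0] == pytest.approx(
            g.at(-39.55, 171.55))

    def test_outside_extent_is_missing(self):
        g = self._plane_grid()
        assert np.isnan(g.at(-50.0, 171.5))

    def test_ascii_round_trip(self, tmp_path):
        g = self._plane_grid()
        p = tmp_path / "g.asc"
        hdr = (f"ncols 20\nnrows 20\nxllcorner {g.xllcorner}\n"
               f"yllcorner {g.yllcorner}\ncellsize {g.cellsize}\n"
               f"NODATA_value -9999\n")
        body = "\n".join(" ".join(f"{v:.3f}" for v in row) for row in g.values)
        p.write_text(hdr + body + "\n")
        g2 = cov.DepthGrid.from_ascii(p)
        np.testing.assert_allclose(g2.values, g.values, atol=1e-3)


class TestLightCondition:
    """The rule, checked on nights bracketing catalogued syzygies.

    2009-07-22 02:35 UTC was a total solar eclipse (new moon): the following
    NZ night is certainly dark.  2000-01-21 04:44 UTC was a total lunar
    eclipse (full moon): the surrounding NZ nights are certainly moonlit.
    """
    LATLON = (-39.0, 172.5)

    def test_daylight_haul_is_light_regardless_of_moon(self):
        assert cov.classify_light_condition(
            pd.Timestamp("2009-07-22 14:00"), *self.LATLON) == "light"
        assert cov.classify_light_condition(
            pd.Timestamp("2000-01-21 14:00"), *self.LATLON) == "light"

    def test_evening_dark_night_is_dark(self):
        assert cov.classify_light_condition(
            pd.Timestamp("2009-07-22 22:00"), *self.LATLON) == "dark"

    def test_after_midnight_dark_night_is_black(self):
        assert cov.classify_light_condition(
            pd.Timestamp("2009-07-23 02:00"), *self.LATLON) == "black"

    def test_after_midnight_moonlit_night_is_dark(self):
        assert cov.classify_light_condition(
            pd.Timestamp("2000-01-22 02:00"), *self.LATLON) == "dark"

    def test_evening_moonlit_night_is_light(self):
        assert cov.classify_light_condition(
            pd.Timestamp("2000-01-21 22:00"), *self.LATLON) == "light"

    def test_partition_every_haul_gets_exactly_one_level(self):
        times = pd.date_range("2004-05-17 00:00", "2004-05-20 23:00", freq="h")
        out = cov.classify_light_condition(times, *self.LATLON)
        assert set(np.unique(out)) <= set(cov.LIGHT_LEVELS)
        assert len(out) == len(times)


class TestNightHours:
    LATLON = (-39.0, 172.5)

    def test_all_daylight_tow_has_zero_night_hours(self):
        assert cov.night_hours(pd.Timestamp("2003-12-01 10:00"),
                               pd.Timestamp("2003-12-01 14:00"),
                               *self.LATLON) == 0.0

    def test_dusk_to_dawn_tow_counts_whole_night(self):
        from bycatch import astro
        _, dusk = astro.civil_twilight_times("2003-06-10", *self.LATLON)
        dawn, _ = astro.civil_twilight_times("2003-06-11", *self.LATLON)
        full = (dawn - dusk).total_seconds() / 3600.0
        got = cov.night_hours(dusk, dawn, *self.LATLON)
        assert got == pytest.approx(full, abs=2e-3)

    def test_straddling_dusk_by_one_hour(self):
        from bycatch import astro
        _, dusk = astro.civil_twilight_times("2003-06-10", *self.LATLON)
        got = cov.night_hours(dusk - pd.Timedelta("3h"),
                              dusk + pd.Timedelta("1h"), *self.LATLON)
        assert got == pytest.approx(1.0, abs=2e-3)


class TestDesignMatrix:
    def _frame(self):
        f = make_effort_frame(3, catch_weight=[0.0, 4.0, 10.0])
        f["observed"] = [True, True, False]
        f["captures"] = [2.0, 0.0, np.nan]
        return cov.derive_covariates(f)

    def test_log_offset_of_zero_catch_is_zero(self):
        specs = [cov.CovariateSpec("log_catch_weight", "catch_weight",
                                   transform="log_offset", offset=1.0)]
        d = cov.build_design_matrix(self._frame(), specs)
        assert d.X["log_catch_weight"].iloc[0] == 0.0

    def test_log_duration_value(self):
        d = cov.build_design_matrix(self._frame(),
                                    [cov.CovariateSpec("log_dur", "tow_duration_h",
                                                       transform="log")])
        assert d.X["log_dur"].iloc[0] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_factor_treatment_coding_against_reference(self):
        f = self._frame()
        f["light_condition"] = ["light", "dark", "black"]
        d = cov.build_design_matrix(
            f, [cov.CovariateSpec("light_condition", "light_condition",
                                  transform="factor",
                                  levels=("dark", "light", "black"))])
        assert list(d.X["light_condition[light]"]) == [1.0, 0.0, 0.0]
        assert list(d.X["light_condition[black]"]) == [0.0, 0.0, 1.0]

    def test_rows_with_underivable_covariates_excluded(self):
        f = self._frame()
        f.loc[0, "headline_depth"] = np.nan
        d = cov.build_design_matrix(
            f, [cov.CovariateSpec("headline_depth", "headline_depth")])
        assert len(d.X) == 2 and d.n_excluded == 1

    def test_all_rows_excluded_is_error(self):
        f = self._frame()
        f["headline_depth"] = np.nan
        with pytest.raises(ValueError, match="empty design"):
            cov.build_design_matrix(
                f, [cov.CovariateSpec("headline_depth", "headline_depth")])

    def test_unobserved_rows_have_undefined_response(self):
        d = cov.build_design_matrix(self._frame())
        assert d.y[0] == 1.0 and d.y[1] == 0.0 and np.isnan(d.y[2])
        assert np.isnan(d.counts[2])
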