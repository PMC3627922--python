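import numpy as np
import pytest
import shapely
from shapely.geometry import box

import terroirgrid as tg
from terroirgrid.soils import (
    DRAINAGE_CODES,
    dominant_condition,
    mapunit_attribute,
)


def tiny_survey():
    mu = box(0, 0, 200, 200)
    comps = [
        tg.Component("m1", "c1", 45.0, "WD", 108.0),
        tg.Component("m1", "c2", 35.0, "SPD", None),
        tg.Component("m1", "c3", 20.0, "WD", 0.0),
    ]
    horizons = [
        tg.Horizon("c1", 0, 30, awc=0.2, ph=6.0),
        tg.Horizon("c1", 30, 60, awc=0.1, ph=7.5),
        tg.Horizon("c2", 0, 100, awc=0.15, ph=7.0),
        tg.Horizon("c3", 0, 10, awc=0.25, ph=5.0),
    ]
    return tg.SoilSurvey([("m1", mu)], comps, horizons)


class TestDominantComponent:
    def test_largest_percent_wins(self):
        assert tg.select_dominant_component(tiny_survey(), "m1") == "c1"

    def test_single_component_is_itself(self):
        s = tg.SoilSurvey([("m", box(0, 0, 1, 1))],
                          [tg.Component("m", "only", 100.0, "WD")], [])
        assert tg.select_dominant_component(s, "m") == "only"

    def test_tie_breaks_to_smallest_cokey(self):
        s = tg.SoilSurvey([("m", box(0, 0, 1, 1))],
                          [tg.Component("m", "B", 50.0, "WD"),
                           tg.Component("m", "A", 50.0, "SPD")], [])
        assert tg.select_dominant_component(s, "m") == "A"

    def test_unknown_mukey_rejected(self):
        with pytest.raises(KeyError, match="unknown mukey"):
            tg.select_dominant_component(tiny_survey(), "nope")

    def test_dominant_condition_sums_class_percents(self):
        # WD components total 65 > SPD 35 even though no single WD dominates
        s = tg.SoilSurvey([("m", box(0, 0, 1, 1))],
                          [tg.Component("m", "a", 33.0, "WD"),
                           tg.Component("m", "b", 32.0, "WD"),
                           tg.Component("m", "c", 35.0, "SPD")], [])
        assert tg.select_dominant_component(s, "m") == "c"
        assert dominant_condition(s, "m") == "WD"


class TestDepthWeightedMean:
    def test_two_horizon_window(self):
        hz = [tg.Horizon("c", 0, 30, awc=0.2), tg.Horizon("c", 30, 60, awc=0.1)]
        assert tg.depth_weighted_mean(hz, "awc") == pytest.approx(0.16)

    def test_single_covering_horizon_identity(self):
        hz = [tg.Horizon("c", 0, 100, ph=7.0)]
        assert tg.depth_weighted_mean(hz, "ph") == pytest.approx(7.0)

    def test_partial_coverage_weights_covered_depth_only(self):
        hz = [tg.Horizon("c", 0, 10, ph=5.0)]
        assert tg.depth_weighted_mean(hz, "ph") == pytest.approx(5.0)

    def test_no_coverage_returns_none(self):
        hz = [tg.Horizon("c", 60, 80, awc=0.1)]
        assert tg.depth_weighted_mean(hz, "awc") is None

    def test_missing_values_excluded_from_denominator(self):
        hz = [tg.Horizon("c", 0, 25, awc=0.2), tg.Horizon("c", 25, 50, awc=None)]
        assert tg.depth_weighted_mean(hz, "awc") == pytest.approx(0.2)

    def test_result_within_contributing_range(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            edges = np.sort(rng.uniform(0, 80, 4))
            hz = [tg.Horizon("c", a, b, awc=float(rng.uniform(0.05, 0.25)))
                  for a, b in zip(edges[:-1], edges[1:]) if b - a > 1e-9]
            out = tg.depth_weighted_mean(hz, "awc")
            if out is not None:
                contributing = [h.awc for h in hz if min(h.bottom, 50) > max(h.top, 0)]
                assert min(contributing) - 1e-12 <= out <= max(contributing) + 1e-12


class TestDepthToRestrictive:
    def test_recorded_depth_returned(self):
        assert tg.depth_to_restrictive(tiny_survey(), "c1") == 108.0

    def test_absent_depth_censored_to_survey_max(self):
        assert tg.depth_to_restrictive(tiny_survey(), "c2") == 200.0

    def test_surface_restriction_zero(self):
        assert tg.depth_to_restrictive(tiny_survey(), "c3") == 0.0

    def test_unknown_cokey_rejected(self):
        with pytest.raises(KeyError, match="unknown cokey"):
            tg.depth_to_restrictive(tiny_survey(), "zz")


class TestRasterize:
    def test_single_mapunit_constant_grid(self):
        s = tiny_survey()
        g = tg.rasterize_attribute(s, "awc", cell=50.0, extent=(0, 0, 200, 200))
        # dominant c1: (30*0.2 + 20*0.1)/50 = 0.16
        assert np.allclose(g.values, 0.16)

    def test_two_halfplane_mapunits_split_at_boundary(self):
        comps = [tg.Component("L", "l1", 100.0, "WD", 50.0),
                 tg.Component("R", "r1", 100.0, "SPD", 150.0)]
        s = tg.SoilSurvey([("L", box(0, 0, 100, 200)), ("R", box(100, 0, 200, 200))],
                          comps, [])
        g = tg.rasterize_attribute(s, "depth", cell=20.0, extent=(0, 0, 200, 200))
        assert set(np.unique(g.values)) == {50.0, 150.0}
        assert np.allclose(g.values[:, :5], 50.0)
        assert np.allclose(g.values[:, 5:], 150.0)

    def test_outside_all_mapunits_is_nodata(self):
        s = tiny_survey()
        g = tg.rasterize_attribute(s, "ph", cell=50.0, extent=(0, 0, 400, 200))
        assert g.nodata_mask[:, 4:].all()
        assert not g.nodata_mask[:, :4].any()

    def test_matches_point_in_polygon_oracle(self):
        cfg = tg.FixtureConfig(seed=9, n_mapunits=5, shape=(20, 20))
        survey = tg.make_soil_survey(cfg)
        extent = (cfg.origin[0], cfg.origin[1] - 600, cfg.origin[0] + 600, cfg.origin[1])
        g = tg.rasterize_attribute(survey, "drainage_class", cell=30.0, extent=extent)
        # brute force over all 400 cell centers
        for r in range(20):
            for c in range(20):
                x, y = g.transform.cell_center(r, c)
                expected = np.nan
                for mukey, geom in survey.mapunits:
                    if shapely.contains_xy(geom, x, y):
                        dom = tg.select_dominant_component(survey, mukey)
                        expected = DRAINAGE_CODES[survey.component(dom).drainage_class]
                        break
                if np.isnan(expected):
                    assert g.nodata_mask[r, c]
                else:
                    assert g.values[r, c] == expected

    def test_deterministic_across_runs(self):
        cfg = tg.FixtureConfig(seed=4, n_mapunits=4, shape=(15, 15))
        survey = tg.make_soil_survey(cfg)
        a = tg.rasterize_attribute(survey, "awc", cell=30.0)
        b = tg.rasterize_attribute(survey, "awc", cell=30.0)
        assert np.array_equal(a.data()[~a.nodata_mask], b.data()[~b.nodata_mask])
        assert np.array_equal(a.nodata_mask, b.nodata_mask)

    def test_unknown_attribute_rejected(self):
        with pytest.raises(ValueError, match="unknown attribute"):
            tg.rasterize_attribute(tiny_survey(), "texture")

    def test_single_unit_proportions_are_pure(self):
        s = tiny_survey()
        g = tg.rasterize_attribute(s, "drainage_class", cell=20.0, extent=(0, 0, 200, 200))
        zones = tg.ZoneSet([("m1", box(0, 0, 200, 200))], crs_tag=s.crs_tag)
        g.crs_tag = s.crs_tag
        props = tg.zonal_class_proportions(g, zones)
        assert props["m1"][DRAINAGE_CODES["WD"]] == pytest.approx(1.0)


class TestSurveyValidation:
    def test_overlapping_horizons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            tg.SoilSurvey([("m", box(0, 0, 1, 1))],
                          [tg.Component("m", "c", 100.0, "WD")],
                          [tg.Horizon("c", 0, 40, awc=0.1),
                           tg.Horizon("c", 30, 60, awc=0.1)])

    def test_percent_overflow_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            tg.SoilSurvey([("m", box(0, 0, 1, 1))],
                          [tg.Component("m", "a", 70.0, "WD"),
                           tg.Component("m", "b", 40.0, "WD")], [])

    def test_unknown_drainage_class_rejected(self):
        with pytest.raises(ValueError, match="drainage"):
            tg.Component("m", "c", 50.0, "XX")


def test_survey_io_round_trip(tmp_path):
    s = tiny_survey()
    paths = [tmp_path / n for n in ("mu.geojson", "comp.csv", "hz.csv")]
    tg.write_soil_survey(s, *paths)
    back = tg.load_soil_survey(*paths)
    assert back.mukeys == s.mukeys
    assert [(c.cokey, c.percent, c.drainage_class, c.depth_to_restrictive)
            for c in back.components] == \
           [(c.cokey, c.percent, c.drainage_class, c.depth_to_restrictive)
            for c in s.components]
    assert mapunit_attribute(back, "m1", "awc") == pytest.approx(0.16)
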