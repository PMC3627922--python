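import math

import numpy as np
import pytest

import terroirgrid as tg
from terroirgrid.solar import declination, mean_latitude


def oracle_direct_flat(params, elevation=0.0):
    """Independent seasonal direct-beam integration on a horizontal surface.

    Coded from the declination / hour-angle definitions, independent of the
    solar module's vectorized path, over the same (day, hour) lattice.
    """
    lat = math.radians(params.latitude)
    total = 0.0
    day = params.day_start
    while day <= params.day_end:
        dec = math.radians(23.45 * math.sin(2 * math.pi * (284 + day) / 365))
        hour = 0.0
        while hour < 24.0:
            ha = math.radians(15.0 * (hour - 12.0))
            cos_z = (math.sin(lat) * math.sin(dec)
                     + math.cos(lat) * math.cos(dec) * math.cos(ha))
            if cos_z > 0:
                m = math.exp(-0.000118 * elevation) / cos_z
                total += (params.solar_constant * params.transmissivity ** m
                          * cos_z * params.hour_step * params.day_step)
            hour += params.hour_step
        day += params.day_step
    return total


class TestSunPositions:
    def test_day_lattice_has_sixteen_days(self):
        params = tg.SolarParams(latitude=46.0)
        pos = tg.sun_positions(params)
        assert len(set(pos["day"])) == 16

    def test_midnight_excluded(self):
        params = tg.SolarParams(latitude=46.0)
        pos = tg.sun_positions(params)
        assert 0.0 not in pos["hour"]
        assert (pos["zenith"] < 90.0).all()

    def test_equator_noon_zenith_tracks_declination(self):
        params = tg.SolarParams(latitude=0.0, day_start=81, day_end=81)
        pos = tg.sun_positions(params)
        noon = pos[pos["hour"] == 12.0]
        assert abs(noon["zenith"][0] - abs(declination(81))) < 0.5


class TestHorizonAngles:
    def test_flat_dem_zero_horizon(self, plane_dem):
        dem = plane_dem(0.0, 0.0)
        hz = tg.compute_horizon_angles(dem, tg.SolarParams(latitude=46.0), 200.0)
        assert np.allclose(hz.angles, 0.0, atol=1e-10)

    def test_wall_obstruction_angle(self, small_transform):
        # wall of height h in the column d meters east of the test cell
        z = np.zeros((5, 9))
        z[:, 7] = 60.0
        dem = tg.Grid(z, small_transform, "EPSG:32611")
        hz = tg.compute_horizon_angles(dem, tg.SolarParams(latitude=46.0), 300.0)
        east = np.where(hz.azimuths == 90.0)[0][0]
        d = 4 * 30.0  # cell (2,3) to wall column 7
        assert hz.angles[2, 3, east] == pytest.approx(math.degrees(math.atan(60.0 / d)),
                                                      abs=1e-9)

    def test_matches_bruteforce_ray_walk(self, small_transform):
        rng = np.random.default_rng(19)
        z = rng.uniform(0, 80, (20, 20))
        dem = tg.Grid(z, small_transform, "EPSG:32611")
        params = tg.SolarParams(latitude=46.0)
        max_radius = 250.0
        hz = tg.compute_horizon_angles(dem, params, max_radius)
        r0, c0 = 9, 11
        cell = 30.0
        for k, az in enumerate(hz.azimuths):
            east, north = math.sin(math.radians(az)), math.cos(math.radians(az))
            best = 0.0
            dist = cell
            while dist <= max_radius + 0.5 * cell:
                fr = r0 - north * dist / cell
                fc = c0 + east * dist / cell
                if 0 <= fr <= 19 and 0 <= fc <= 19:
                    i0, j0 = int(math.floor(fr)), int(math.floor(fc))
                    i1, j1 = min(i0 + 1, 19), min(j0 + 1, 19)
                    wr, wc = fr - i0, fc - j0
                    zs = ((1 - wr) * (1 - wc) * z[i0, j0] + (1 - wr) * wc * z[i0, j1]
                          + wr * (1 - wc) * z[i1, j0] + wr * wc * z[i1, j1])
                    best = max(best, math.degrees(math.atan((zs - z[r0, c0]) / dist)))
                dist += cell
            assert hz.angles[r0, c0, k] == pytest.approx(best, abs=1e-10)

    def test_radius_below_one_cell_rejected(self, plane_dem):
        with pytest.raises(ValueError, match="one cell"):
            tg.compute_horizon_angles(plane_dem(0, 0), tg.SolarParams(latitude=46.0), 5.0)


class TestInsolation:
    def test_fully_obstructed_is_zero(self, plane_dem):
        dem = plane_dem(0.0, 0.0)
        params = tg.SolarParams(latitude=46.0)
        hz = tg.HorizonSet(np.full(dem.shape + (32,), 90.0),
                           params.viewshed_azimuths)
        out = tg.compute_insolation(dem, tg.compute_slope(dem),
                                    tg.compute_aspect(dem), hz, params)
        assert np.allclose(out.values, 0.0)

    def test_flat_unobstructed_matches_oracle(self, plane_dem):
        dem = plane_dem(0.0, 0.0, base=200.0, shape=(8, 8))
        params = tg.SolarParams(latitude=46.5)
        hz = tg.compute_horizon_angles(dem, params, 100.0)
        out = tg.compute_insolation(dem, tg.compute_slope(dem),
                                    tg.compute_aspect(dem), hz, params)
        direct = oracle_direct_flat(params, elevation=200.0)
        expected = direct / (1.0 - params.diffuse_proportion)
        assert out.values[4, 4] == pytest.approx(expected, rel=0.005)

    def test_direct_only_closed_form(self, plane_dem):
        # diffuse off and perfectly transparent sky: S0 * sum cos(z) * dt
        dem = plane_dem(0.0, 0.0, base=0.0, shape=(6, 6))
        params = tg.SolarParams(latitude=46.5, diffuse_proportion=1e-9,
                                transmissivity=1.0)
        hz = tg.compute_horizon_angles(dem, params, 100.0)
        out = tg.compute_insolation(dem, tg.compute_slope(dem),
                                    tg.compute_aspect(dem), hz, params)
        pos = tg.sun_positions(params)
        closed = (params.solar_constant
                  * np.sum(np.cos(np.radians(pos["zenith"])))
                  * params.hour_step * params.day_step)
        assert out.values[3, 3] == pytest.approx(closed, rel=0.001)

    def test_south_facing_exceeds_north_facing(self, plane_dem):
        dem = plane_dem(0.0, 0.0, shape=(6, 6))
        params = tg.SolarParams(latitude=46.0)
        hz = tg.compute_horizon_angles(dem, params, 100.0)
        slope = tg.compute_slope(dem).with_values(np.full(dem.shape, 20.0))
        south = tg.compute_aspect(dem).with_values(np.full(dem.shape, 180.0))
        north = tg.compute_aspect(dem).with_values(np.full(dem.shape, 0.0))
        s_val = tg.compute_insolation(dem, slope, south, hz, params).values[3, 3]
        n_val = tg.compute_insolation(dem, slope, north, hz, params).values[3, 3]
        assert s_val > n_val

    def test_hour_lattice_refinement_converges(self, plane_dem):
        dem = plane_dem(0.0, 0.0, shape=(4, 4))
        values = {}
        for step in (4.0, 2.0, 1.0, 0.5):
            params = tg.SolarParams(latitude=46.0, hour_step=step)
            hz = tg.HorizonSet(np.zeros(dem.shape + (32,)), params.viewshed_azimuths)
            out = tg.compute_insolation(dem, tg.compute_slope(dem),
                                        tg.compute_aspect(dem), hz, params)
            values[step] = out.values[2, 2]
        err_coarse = abs(values[4.0] - values[0.5])
        err_fine = abs(values[1.0] - values[0.5])
        assert err_fine < err_coarse


class TestTilingAndMosaic:
    def test_small_dem_single_tile_identity(self, plane_dem):
        dem = plane_dem(0.01, 0.02, shape=(20, 10))
        tiles = tg.tile_by_latitude(dem, max_extent_deg=1.0, overlap=60.0)
        assert len(tiles) == 1
        assert np.array_equal(tiles[0].values, dem.values)

    def test_two_tiles_share_overlap_strip(self, plane_dem):
        dem = plane_dem(0.0, 0.01, shape=(40, 10))
        span_deg = 40 * 30.0 / 111_320.0
        tiles = tg.tile_by_latitude(dem, span_deg / 1.9, overlap=150.0)
        assert len(tiles) == 2
        (s0, e0), (s1, e1) = (t.meta["tile_rows"] for t in tiles)
        assert e0 - s1 == 5  # 150 m / 30 m shared rows
        shared = dem.values[s1:e0]
        assert np.array_equal(tiles[0].values[s1 - s0:], shared)
        assert np.array_equal(tiles[1].values[: e0 - s1], shared)

    def test_tiles_cover_extent_exactly(self, plane_dem):
        dem = plane_dem(0.0, 0.01, shape=(50, 8))
        span_deg = 50 * 30.0 / 111_320.0
        tiles = tg.tile_by_latitude(dem, span_deg / 2.6, overlap=90.0)
        covered = np.zeros(50, bool)
        for t in tiles:
            s, e = t.meta["tile_rows"]
            covered[s:e] = True
        assert covered.all()

    def test_oversized_overlap_rejected(self, plane_dem):
        dem = plane_dem(0.0, 0.01, shape=(40, 8))
        span_deg = 40 * 30.0 / 111_320.0
        with pytest.raises(ValueError, match="overlap"):
            tg.tile_by_latitude(dem, span_deg / 1.9, overlap=700.0)

    def test_identical_tiles_blend_to_same_values(self, plane_dem):
        dem = plane_dem(0.01, 0.02, shape=(40, 10))
        span_deg = 40 * 30.0 / 111_320.0
        tiles = tg.tile_by_latitude(dem, span_deg / 1.9, overlap=150.0)
        mosaic = tg.blend_mosaic(tiles)
        assert np.allclose(mosaic.values, dem.values, atol=1e-9)

    def test_ramp_midpoint_averages_and_stays_convex(self, small_transform):
        # two constant tiles a=10, b=20 with a 4-row overlap
        t = small_transform
        a = tg.Grid(np.full((10, 6), 10.0), t, "EPSG:32611", meta={"tile_rows": (0, 10)})
        t2 = tg.GridTransform(t.x0, t.y0 + 6 * t.dy, t.dx, t.dy)
        b = tg.Grid(np.full((10, 6), 20.0), t2, "EPSG:32611", meta={"tile_rows": (6, 16)})
        mosaic = tg.blend_mosaic([a, b])
        overlap = mosaic.values[6:10]
        assert ((overlap >= 10.0) & (overlap <= 20.0)).all()
        assert mosaic.values[7, 0] + mosaic.values[8, 0] == pytest.approx(30.0)
        assert np.allclose(mosaic.values[:6], 10.0)
        assert np.allclose(mosaic.values[10:], 20.0)

    def test_gap_between_tiles_rejected(self, small_transform):
        t = small_transform
        a = tg.Grid(np.zeros((5, 4)), t, "EPSG:32611", meta={"tile_rows": (0, 5)})
        t2 = tg.GridTransform(t.x0, t.y0 + 7 * t.dy, t.dx, t.dy)
        b = tg.Grid(np.zeros((5, 4)), t2, "EPSG:32611", meta={"tile_rows": (7, 12)})
        with pytest.raises(ValueError, match="gap"):
            tg.blend_mosaic([a, b])

    def test_band_mean_latitude_tracks_row_offset(self, plane_dem):
        dem = plane_dem(0.0, 0.0, shape=(40, 8))
        y_ref = dem.transform.y0 + 0.5 * 40 * dem.transform.dy
        span_deg = 40 * 30.0 / 111_320.0
        tiles = tg.tile_by_latitude(dem, span_deg / 1.9, overlap=60.0)
        lats = [mean_latitude(t, 46.5, y_ref) for t in tiles]
        assert lats[0] > 46.5 > lats[-1]  # northern band sits at higher latitude
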