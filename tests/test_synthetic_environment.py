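"""Synthetic environment generators: fields, bathymetry, hexagon maps."""

import numpy as np
import pytest

from reefconnect.synthetic_environment import (
    DEPTH_AVG_2D,
    FULL_3D,
    HABITAT_ZONES,
    SURFACE_2D,
    BathymetryField,
    GridSpec,
    HexagonMap,
    VelocityFieldSet,
    derive_depth_averaged,
    derive_surface,
    make_drift_tide_field,
    make_hexagon_map,
    make_reef_bathymetry,
)


class TestGridSpec:
    def test_rejects_non_uniform_axis(self):
        with pytest.raises(ValueError, match="uniform"):
            GridSpec(
                x_coords=np.array([0.0, 1.0, 3.0]),
                y_coords=np.array([0.0, 1.0]),
                layer_interfaces=np.array([0.0, 1.0]),
                time_points=np.array([0.0, 1.0]),
            )

    def test_rejects_nonzero_first_interface(self):
        with pytest.raises(ValueError, match="surface"):
            GridSpec(
                x_coords=np.array([0.0, 1.0]),
                y_coords=np.array([0.0, 1.0]),
                layer_interfaces=np.array([1.0, 2.0]),
                time_points=np.array([0.0, 1.0]),
            )

    def test_layer_midpoints_and_thickness(self, small_grid):
        assert np.allclose(small_grid.layer_midpoints, [0.5, 3.0, 12.5])
        assert np.allclose(small_grid.layer_thickness, [1.0, 4.0, 15.0])


class TestDriftTideField:
    def test_constant_drift(self, single_layer_grid):
        f = make_drift_tide_field(
            single_layer_grid, mean_u=-0.1, mean_v=0.0, tidal_amp=0.0,
            tidal_period=12.0, shear=[1.0],
        )
        assert np.all(f.u == -0.1)
        assert np.all(f.v == 0.0)

    def test_sine_zeros_at_nodes(self, single_layer_grid):
        f = make_drift_tide_field(
            single_layer_grid, mean_u=0.0, mean_v=0.0, tidal_amp=0.3,
            tidal_period=12.0, shear=[1.0],
        )
        # sin(0) and sin(pi): t = 0 h and t = 6 h
        assert abs(f.u[0]).max() < 1e-12
        assert abs(f.u[6]).max() < 1e-12

    def test_zero_shear_layer_is_still(self, small_grid):
        f = make_drift_tide_field(
            small_grid, mean_u=-0.1, mean_v=0.0, tidal_amp=0.05,
            tidal_period=12.0, shear=[1.0, 0.5, 0.0],
        )
        assert np.all(f.u[:, 2] == 0.0)
        assert np.all(f.u[:, 1] == 0.5 * f.u[:, 0])

    def test_time_average_over_whole_periods_is_mean_drift(self, small_grid):
        shear = [1.0, 0.7, 0.3]
        f = make_drift_tide_field(
            small_grid, mean_u=-0.08, mean_v=0.02, tidal_amp=0.25,
            tidal_period=12.0, shear=shear,
        )
        # 48 hourly samples span 4 whole 12-h periods; sample mean of the
        # sine over a period's equispaced points is exactly zero
        for k, s in enumerate(shear):
            assert np.allclose(f.u[:48, k].mean(), -0.08 * s, atol=1e-12)
            assert np.allclose(f.v[:48, k].mean(), 0.02 * s, atol=1e-12)

    def test_anisotropic_tide(self, single_layer_grid):
        f = make_drift_tide_field(
            single_layer_grid, mean_u=0.0, mean_v=0.0, tidal_amp=0.3,
            tidal_period=12.0, shear=[1.0], tidal_amp_v=0.0,
        )
        assert np.all(f.v == 0.0)
        assert abs(f.u[3]).max() > 0.29  # near sine peak

    def test_rejects_bad_period_and_shear(self, single_layer_grid):
        with pytest.raises(ValueError, match="period"):
            make_drift_tide_field(
                single_layer_grid, 0.0, 0.0, 0.1, tidal_period=0.0, shear=[1.0]
            )
        with pytest.raises(ValueError, match="shear"):
            make_drift_tide_field(
                single_layer_grid, 0.0, 0.0, 0.1, tidal_period=12.0, shear=[1.0, 0.5]
            )

    def test_land_cells_are_still(self, single_layer_grid):
        depth = np.full((21, 21), 30.0)
        depth[:3, :3] = -1.0
        bathy = BathymetryField(grid=single_layer_grid, depth=depth)
        f = make_drift_tide_field(
            single_layer_grid, mean_u=-0.1, mean_v=0.0, tidal_amp=0.0,
            tidal_period=12.0, shear=[1.0], bathymetry=bathy,
        )
        assert np.all(f.u[:, :, :3, :3] == 0.0)
        assert np.all(f.u[:, :, 5:, 5:] == -0.1)


class TestReefBathymetry:
    def test_no_platforms_uniform(self, small_grid):
        b = make_reef_bathymetry(small_grid, [], background_depth=45.0)
        assert np.all(b.depth == 45.0)

    def test_crest_depth_at_platform(self, small_grid):
        b = make_reef_bathymetry(
            small_grid, [((0.0, 0.0), 1_000.0, 2.0)], background_depth=45.0
        )
        assert b.depth.min() == pytest.approx(2.0)
        iy = np.argmin(np.abs(small_grid.y_coords))
        ix = np.argmin(np.abs(small_grid.x_coords))
        assert b.depth[iy, ix] == pytest.approx(2.0)
        # far corner untouched
        assert b.depth[0, 0] == pytest.approx(45.0)

    def test_monotone_ramp(self, small_grid):
        b = make_reef_bathymetry(
            small_grid, [((0.0, 0.0), 1_000.0, 2.0)], background_depth=45.0
        )
        iy = np.argmin(np.abs(small_grid.y_coords))
        row = b.depth[iy]
        east = row[len(row) // 2:]
        assert np.all(np.diff(east) >= -1e-9)

    def test_overlapping_minimum_and_zero_radius(self, small_grid):
        with pytest.raises(ValueError, match="radius"):
            make_reef_bathymetry(small_grid, [((0, 0), 0.0, 2.0)], 45.0)
        b = make_reef_bathymetry(
            small_grid,
            [((0.0, 0.0), 1_000.0, 5.0), ((500.0, 0.0), 1_000.0, 2.0)],
            background_depth=45.0,
        )
        assert b.depth.min() == pytest.approx(2.0)


class TestHexagonMap:
    @pytest.mark.parametrize("n_rings", [1, 2, 3, 5])
    def test_count_closed_form_and_area(self, n_rings):
        m = make_hexagon_map(n_rings=n_rings, hex_area=1_000.0, seed=0)
        expected = 1 + 3 * n_rings * (n_rings + 1)
        assert len(m) == expected
        assert m.total_area == pytest.approx(expected * 1_000.0)

    def test_zone_labels_valid_and_non_contiguous(self):
        m = make_hexagon_map(n_rings=5, hex_area=1_000.0, seed=0)
        zones = {h.zone for h in m.hexagons}
        assert zones <= set(HABITAT_ZONES)
        # default rule cycles zones by ring: ReefCrest sits on rings 1 and 5,
        # separated by other zones -> spatially non-contiguous patches
        crest_rings = set()
        for h in m.hexagons:
            if h.zone == "ReefCrest":
                r = np.hypot(*h.centroid)
                crest_rings.add(round(r / 100.0))
        assert len(crest_rings) > 1

    def test_depth_increases_with_distance(self):
        m = make_hexagon_map(n_rings=4, hex_area=1_000.0, seed=3, depth_jitter=0.0)
        d = np.array([h.depth for h in m.hexagons])
        r = np.array([np.hypot(*h.centroid) for h in m.hexagons])
        assert np.corrcoef(d, r)[0, 1] > 0.99

    def test_hexagon_geometry_area(self):
        from shapely.geometry import Polygon

        m = make_hexagon_map(n_rings=1, hex_area=2_500.0, seed=0)
        for h in m.hexagons:
            assert Polygon(h.vertices).area == pytest.approx(2_500.0, rel=1e-9)

    def test_geojson_roundtrip(self, tmp_path):
        m = make_hexagon_map(n_rings=2, hex_area=1_000.0, seed=1)
        p = tmp_path / "hex.geojson"
        m.to_geojson(p)
        m2 = HexagonMap.from_geojson(p)
        assert len(m2) == len(m)
        for a, b in zip(m.hexagons, m2.hexagons):
            assert a.hex_id == b.hex_id
            assert a.zone == b.zone
            assert a.depth == pytest.approx(b.depth)
            assert np.allclose(a.vertices, b.vertices)


class TestDimensionalReductions:
    def _field(self, grid, shear):
        return make_drift_tide_field(
            grid, mean_u=-0.1, mean_v=0.03, tidal_amp=0.2,
            tidal_period=12.0, shear=shear,
        )

    def test_surface_preserves_layer0_bitexact(self, small_grid):
        f = self._field(small_grid, [1.0, 0.5, 0.2])
        s = derive_surface(f)
        assert s.mode == SURFACE_2D
        assert s.grid.n_layers == 1
        assert np.array_equal(s.u[:, 0], f.u[:, 0])

    def test_surface_rejects_2d_input(self, small_grid):
        f = self._field(small_grid, [1.0, 0.5, 0.2])
        with pytest.raises(ValueError):
            derive_surface(derive_surface(f))

    def test_depth_average_uniform_profile(self, small_grid):
        f = self._field(small_grid, [1.0, 1.0, 1.0])
        bathy = make_reef_bathymetry(small_grid, [], background_depth=50.0)
        avg = derive_depth_averaged(f, bathy)
        assert avg.mode == DEPTH_AVG_2D
        assert np.allclose(avg.u[:, 0], f.u[:, 0])

    def test_depth_average_hand_computed_weights(self):
        # layers of thickness 1, 1, 2 m with u = 1, 1, 0: mean = 2/4
        grid = GridSpec(
            x_coords=np.array([0.0, 100.0]),
            y_coords=np.array([0.0, 100.0]),
            layer_interfaces=np.array([0.0, 1.0, 2.0, 4.0]),
            time_points=np.array([0.0, 1.0]),
        )
        u = np.zeros((2, 3, 2, 2))
        u[:, 0] = 1.0
        u[:, 1] = 1.0
        f = VelocityFieldSet(grid=grid, u=u, v=np.zeros_like(u), w=np.zeros_like(u), mode=FULL_3D)
        bathy = BathymetryField(grid=grid, depth=np.full((2, 2), 4.0))
        avg = derive_depth_averaged(f, bathy)
        assert np.allclose(avg.u, 0.5)

    def test_depth_average_two_equal_layers(self):
        grid = GridSpec(
            x_coords=np.array([0.0, 100.0]),
            y_coords=np.array([0.0, 100.0]),
            layer_interfaces=np.array([0.0, 2.0, 4.0]),
            time_points=np.array([0.0, 1.0]),
        )
        u = np.zeros((2, 2, 2, 2))
        u[:, 0] = 1.0
        f = VelocityFieldSet(grid=grid, u=u, v=np.zeros_like(u), w=np.zeros_like(u), mode=FULL_3D)
        bathy = BathymetryField(grid=grid, depth=np.full((2, 2), 4.0))
        assert np.allclose(derive_depth_averaged(f, bathy).u, 0.5)

    def test_depth_average_clips_to_seabed(self):
        # seabed at 1 m: only the top layer contributes
        grid = GridSpec(
            x_coords=np.array([0.0, 100.0]),
            y_coords=np.array([0.0, 100.0]),
            layer_interfaces=np.array([0.0, 1.0, 2.0, 4.0]),
            time_points=np.array([0.0, 1.0]),
        )
        u = np.zeros((2, 3, 2, 2))
        u[:, 0] = 0.3
        u[:, 1] = 1.0
        f = VelocityFieldSet(grid=grid, u=u, v=np.zeros_like(u), w=np.zeros_like(u), mode=FULL_3D)
        bathy = BathymetryField(grid=grid, depth=np.full((2, 2), 1.0))
        assert np.allclose(derive_depth_averaged(f, bathy).u, 0.3)

    def test_zero_water_column_becomes_land(self):
        grid = GridSpec(
            x_coords=np.array([0.0, 100.0]),
            y_coords=np.array([0.0, 100.0]),
            layer_interfaces=np.array([0.0, 1.0]),
            time_points=np.array([0.0, 1.0]),
        )
        depth = np.array([[0.0, 4.0], [4.0, 4.0]])
        u = np.full((2, 1, 2, 2), 0.5)
        u[:, :, 0, 0] = 0.0  # land cell must be still already
        f = VelocityFieldSet(
            grid=grid, u=u, v=np.zeros_like(u), w=np.zeros_like(u),
            mode=FULL_3D, land_mask=depth <= 0,
        )
        avg = derive_depth_averaged(f, BathymetryField(grid=grid, depth=depth))
        assert avg.land_mask[0, 0]
        assert np.all(avg.u[:, :, 0, 0] == 0.0)

    def test_depth_uniform_equals_surface(self, small_grid):
        f = self._field(small_grid, [1.0, 1.0, 1.0])
        bathy = make_reef_bathymetry(small_grid, [], background_depth=50.0)
        assert np.allclose(
            derive_depth_averaged(f, bathy).u, derive_surface(f).u, atol=1e-12
        )


class TestNetcdfRoundtrip:
    def test_roundtrip_3d(self, small_grid, tmp_path):
        f = make_drift_tide_field(
            small_grid, mean_u=-0.1, mean_v=0.02, tidal_amp=0.2,
            tidal_period=12.0, shear=[1.0, 0.5, 0.2],
        )
        p = tmp_path / "field.nc"
        f.to_netcdf(p)
        g = VelocityFieldSet.from_netcdf(p)
        assert g.mode == f.mode
        assert np.allclose(g.u, f.u)
        assert np.allclose(g.grid.layer_interfaces, f.grid.layer_interfaces)
        assert np.array_equal(g.land_mask, f.land_mask)
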