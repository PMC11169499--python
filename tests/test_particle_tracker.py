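"""Advection: interpolation, nesting, RK4 accuracy, tracking bookkeeping."""

import numpy as np
import pytest

from conftest import rotation_field
from reefconnect.particle_tracker import (
    NestedVelocitySampler,
    OutsideDomainError,
    ParticleState,
    TrackerConfig,
    Trajectory,
    _rk4_core,
    accounting,
    sample_velocity,
    step_rk4,
    track,
    trajectories_to_netcdf,
)
from reefconnect.synthetic_environment import (
    BathymetryField,
    FULL_3D,
    GridSpec,
    VelocityFieldSet,
    make_drift_tide_field,
)


def uniform_field(grid, u=0.0, v=0.0, mode=None):
    return make_drift_tide_field(
        grid, mean_u=u, mean_v=v, tidal_amp=0.0, tidal_period=12.0,
        shear=[1.0] * grid.n_layers, mode=mode,
    )


def grid(span=20_000.0, dx=1_000.0, layers=(0.0, 5.0), hours=48):
    return GridSpec(
        x_coords=np.arange(-span, span + 1, dx),
        y_coords=np.arange(-span, span + 1, dx),
        layer_interfaces=np.array(layers),
        time_points=np.arange(0.0, hours + 1.0),
    )


def nested(fine_field, coarse_field, **kw):
    return NestedVelocitySampler(fine=fine_field, coarse=coarse_field, **kw)


@pytest.fixture
def drift_sampler():
    f = uniform_field(grid(span=10_000.0, dx=500.0), u=0.1)
    c = uniform_field(grid(span=40_000.0, dx=2_000.0), u=0.1)
    return nested(f, c)


class TestSampling:
    def test_nodal_values_exact(self):
        g = grid()
        rng = np.random.default_rng(0)
        u = rng.normal(size=(g.time_points.size, 1, g.y_coords.size, g.x_coords.size))
        f = VelocityFieldSet(grid=g, u=u, v=-u, mode="depthavg2d")
        c = uniform_field(grid(span=40_000.0, dx=2_000.0))
        s = nested(f, c)
        uu, vv, _ = sample_velocity(s, x=g.x_coords[5], y=g.y_coords[7], z=0.0, t=3.0)
        assert uu == pytest.approx(u[3, 0, 7, 5], abs=1e-12)
        assert vv == pytest.approx(-u[3, 0, 7, 5], abs=1e-12)

    def test_time_midpoint_interpolates(self):
        g = grid(hours=2)
        u = np.zeros((3, 1, g.y_coords.size, g.x_coords.size))
        u[1] = 1.0
        f = VelocityFieldSet(grid=g, u=u, v=np.zeros_like(u), mode="depthavg2d")
        c = uniform_field(
            GridSpec(
                x_coords=np.arange(-40_000.0, 40_001.0, 2_000.0),
                y_coords=np.arange(-40_000.0, 40_001.0, 2_000.0),
                layer_interfaces=np.array([0.0, 5.0]),
                time_points=np.arange(0.0, 3.0),
            )
        )
        s = nested(f, c)
        uu, _, _ = sample_velocity(s, 0.0, 0.0, 0.0, t=0.5)
        assert uu == pytest.approx(0.5)

    def test_fine_takes_precedence_inside_fine_bounds(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0), u=1.0)
        c = uniform_field(grid(span=40_000.0, dx=2_000.0), u=-1.0)
        s = nested(f, c)
        assert sample_velocity(s, 0.0, 0.0, 0.0, 1.0)[0] == pytest.approx(1.0)
        assert sample_velocity(s, 20_000.0, 0.0, 0.0, 1.0)[0] == pytest.approx(-1.0)

    def test_outside_domain_raises(self, drift_sampler):
        with pytest.raises(OutsideDomainError):
            sample_velocity(drift_sampler, 1e6, 0.0, 0.0, 1.0)
        with pytest.raises(OutsideDomainError):
            sample_velocity(drift_sampler, 0.0, 0.0, 0.0, 1e5)

    def test_vertical_interpolation_between_midpoints(self):
        g = grid(layers=(0.0, 1.0, 5.0))
        nt, ny, nx = g.time_points.size, g.y_coords.size, g.x_coords.size
        u = np.zeros((nt, 2, ny, nx))
        u[:, 0] = 1.0  # midpoint 0.5 m
        u[:, 1] = 0.0  # midpoint 3.0 m
        f = VelocityFieldSet(grid=g, u=u, v=np.zeros_like(u), w=np.zeros_like(u), mode=FULL_3D)
        c = uniform_field(grid(span=40_000.0, dx=2_000.0, layers=(0.0, 1.0, 5.0)), mode=FULL_3D)
        s = nested(f, c)
        at = lambda z: sample_velocity(s, 0.0, 0.0, z, 1.0)[0]
        assert at(0.5) == pytest.approx(1.0)
        assert at(3.0) == pytest.approx(0.0)
        assert at(1.75) == pytest.approx(0.5)
        assert at(0.0) == pytest.approx(1.0)  # clamped above first midpoint
        assert at(10.0) == pytest.approx(0.0)  # clamped below last midpoint

    def test_fine_bounds_must_nest(self):
        f = uniform_field(grid(span=40_000.0, dx=2_000.0))
        c = uniform_field(grid(span=10_000.0, dx=500.0))
        with pytest.raises(ValueError, match="strictly inside"):
            nested(f, c)


class TestStepRK4:
    def test_uniform_flow_exact(self, drift_sampler):
        p = ParticleState(0, "A", x=0.0, y=0.0, z=1.0, release_time=0.0)
        p2 = step_rk4(p, drift_sampler, dt_minutes=60.0, mode="depthavg2d")
        assert p2.x == pytest.approx(360.0, abs=1e-9)
        assert p2.y == pytest.approx(0.0)
        assert p2.status == "active"

    def test_outward_flow_exits(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0), u=1.0)
        c = uniform_field(grid(span=40_000.0, dx=2_000.0), u=1.0)
        s = nested(f, c)
        p = ParticleState(0, "A", x=39_900.0, y=0.0, z=1.0, release_time=0.0)
        p2 = step_rk4(p, s, dt_minutes=60.0, mode="depthavg2d")
        assert p2.status == "exited"

    def test_rejects_inactive(self, drift_sampler):
        p = ParticleState(0, "A", 0, 0, 1, 0, status="dead")
        with pytest.raises(ValueError):
            step_rk4(p, drift_sampler, 5.0, "depthavg2d")


def _rotation_sampler(omega_per_hour=2 * np.pi / 12.0):
    f = rotation_field(grid(span=10_000.0, dx=500.0, hours=60), omega_per_hour)
    c = rotation_field(grid(span=40_000.0, dx=2_000.0, hours=60), omega_per_hour)
    return nested(f, c)


def orbit_error(sampler, dt_minutes, radius=3_000.0, period_h=12.0):
    """Position error after one full revolution, single particle."""
    n = int(round(period_h * 60.0 / dt_minutes))
    x = np.array([radius])
    y = np.array([0.0])
    z = np.array([1.0])
    for k in range(n):
        t = np.array([k * dt_minutes / 60.0])
        x, y, z, ex = _rk4_core(sampler, x, y, z, t, dt_minutes * 60.0, "depthavg2d")
        assert not ex[0]
    return float(np.hypot(x[0] - radius, y[0]))


class TestRK4Convergence:
    def test_orbit_closes_fourth_order(self):
        s = _rotation_sampler()
        errors = [orbit_error(s, dt) for dt in (30.0, 15.0, 7.5)]
        assert errors[0] < 50.0  # coarse step already sub-grid accuracy
        for e0, e1 in zip(errors, errors[1:]):
            assert 10.0 < e0 / e1 < 24.0  # ~16x per halving


class TestKernelMatchesReference:
    def test_chunked_kernel_equals_numpy_step(self):
        """The compiled advection loop reproduces the vectorized RK4 step."""
        from reefconnect._kernels import advect_chunk
        from reefconnect.particle_tracker import _pack_sampler

        g = grid(span=10_000.0, dx=500.0, layers=(0.0, 1.0, 5.0, 20.0))
        rng = np.random.default_rng(7)
        shape = (g.time_points.size, 3, g.y_coords.size, g.x_coords.size)
        f = VelocityFieldSet(
            grid=g,
            u=0.2 * rng.standard_normal(shape),
            v=0.2 * rng.standard_normal(shape),
            w=0.001 * rng.standard_normal(shape),
            mode=FULL_3D,
        )
        cg = grid(span=40_000.0, dx=2_000.0, layers=(0.0, 1.0, 5.0, 20.0))
        c = uniform_field(cg, u=0.05, mode=FULL_3D)
        s = nested(f, c)
        n = 40
        x0 = rng.uniform(-8_000, 8_000, n)
        y0 = rng.uniform(-8_000, 8_000, n)
        z0 = rng.uniform(0.5, 10.0, n)
        t0 = rng.uniform(0.0, 10.0, n)
        # reference: repeated vectorized steps
        xr, yr, zr = x0.copy(), y0.copy(), z0.copy()
        tr = t0.copy()
        for _ in range(6):
            xr, yr, zr, ex = _rk4_core(s, xr, yr, zr, tr, 300.0, FULL_3D)
            tr += 300.0 / 3600.0
            assert not ex.any()
        # kernel: one chunked call
        xk, yk, zk, tk = x0.copy(), y0.copy(), z0.copy(), t0.copy()
        exited = np.zeros(n, dtype=np.bool_)
        fine_args, coarse_args, fb, cb, t_lo, t_hi, bath_args = _pack_sampler(s)
        advect_chunk(xk, yk, zk, tk, 6, 300.0, True,
                     *fine_args, *coarse_args, fb, cb, t_lo, t_hi, *bath_args, exited)
        assert not exited.any()
        np.testing.assert_allclose(xk, xr, rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(yk, yr, rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(zk, zr, rtol=1e-12, atol=1e-9)


class TestTrack:
    def _particles(self, n=1, x=0.0, y=0.0):
        return [
            ParticleState(i, "A", x=x, y=y, z=2.25, release_time=0.0)
            for i in range(n)
        ]

    def test_zero_flow_one_day(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0))
        c = uniform_field(grid(span=40_000.0, dx=2_000.0))
        cfg = TrackerConfig(duration_days=1.0, mode="depthavg2d")
        trajs = track(self._particles(), nested(f, c), cfg)
        tr = trajs[0]
        assert tr.times.size == 96  # 24 h at 15-min cadence
        assert np.all(tr.x == 0.0) and np.all(tr.y == 0.0)
        assert tr.status == "active"
        assert np.allclose(np.diff(tr.times), 0.25)

    def test_westward_drift_net_displacement(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0), u=-0.1)
        c = uniform_field(grid(span=40_000.0, dx=2_000.0), u=-0.1)
        cfg = TrackerConfig(duration_days=1.0, mode="depthavg2d")
        trajs = track(self._particles(), nested(f, c), cfg)
        assert trajs[0].x[-1] == pytest.approx(-8_640.0, abs=1e-6)

    def test_hook_settles_everything_at_first_record(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0))
        c = uniform_field(grid(span=40_000.0, dx=2_000.0))
        cfg = TrackerConfig(duration_days=1.0, mode="depthavg2d")

        def hook(ids, x, y, age_h, clock):
            return np.zeros(ids.shape, dtype=int)

        trajs = track(
            self._particles(5), nested(f, c), cfg,
            settlement_hook=hook, site_ids=["H"],
        )
        for tr in trajs:
            assert tr.status == "settled"
            assert tr.settle_site == "H"
            assert tr.times.size == 1

    def test_daily_hook_kills(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0))
        c = uniform_field(grid(span=40_000.0, dx=2_000.0))
        cfg = TrackerConfig(duration_days=2.0, mode="depthavg2d")

        def daily(day, active_ids):
            return active_ids[: len(active_ids) // 2]

        trajs = track(self._particles(8), nested(f, c), cfg, daily_hook=daily)
        counts = accounting(trajs)
        assert counts["dead"] == 4 + 2
        assert counts["active"] == 2
        assert counts["released"] == 8

    def test_active_positions_stay_in_domain(self):
        f = uniform_field(grid(span=10_000.0, dx=500.0), u=0.5)
        c = uniform_field(grid(span=40_000.0, dx=2_000.0), u=0.5)
        s = nested(f, c)
        cfg = TrackerConfig(duration_days=2.0, mode="depthavg2d")
        trajs = track(self._particles(3, x=30_000.0), s, cfg)
        xmin, xmax, ymin, ymax = s.coarse_bounds
        for tr in trajs:
            assert tr.status == "exited"
            assert np.all((tr.x >= xmin) & (tr.x <= xmax))

    def test_depth_uniform_3d_matches_depth_averaged(self):
        from reefconnect.synthetic_environment import derive_depth_averaged, make_reef_bathymetry

        g3 = grid(span=10_000.0, dx=500.0, layers=(0.0, 1.0, 5.0, 20.0))
        c3 = grid(span=40_000.0, dx=2_000.0, layers=(0.0, 1.0, 5.0, 20.0))
        mk = lambda gg: make_drift_tide_field(
            gg, mean_u=-0.05, mean_v=0.02, tidal_amp=0.1, tidal_period=12.0,
            shear=[1.0, 1.0, 1.0],
        )
        f3, cc3 = mk(g3), mk(c3)
        b_f = make_reef_bathymetry(g3, [], background_depth=50.0)
        b_c = make_reef_bathymetry(c3, [], background_depth=50.0)
        s3 = nested(f3, cc3, bathymetry=b_f)
        s2 = nested(derive_depth_averaged(f3, b_f), derive_depth_averaged(cc3, b_c),
                    bathymetry=b_f)
        parts = lambda: [
            ParticleState(i, "A", x=500.0 * i, y=-200.0 * i, z=2.25, release_time=0.0)
            for i in range(5)
        ]
        cfg3 = TrackerConfig(duration_days=1.0, mode="full3d")
        cfg2 = TrackerConfig(duration_days=1.0, mode="depthavg2d")
        t3 = track(parts(), s3, cfg3)
        t2 = track(parts(), s2, cfg2)
        for a, b in zip(t3, t2):
            np.testing.assert_allclose(a.x, b.x, rtol=1e-9)
            np.testing.assert_allclose(a.y, b.y, rtol=1e-9)

    def test_nested_handoff_matches_single_grid(self):
        """Identical analytic flow on both grids: crossing the fine
        boundary leaves the trajectory within integrator tolerance of a
        coarse-only solution."""
        omega = 2 * np.pi / 24.0
        f = rotation_field(grid(span=5_000.0, dx=500.0, hours=60), omega)
        c = rotation_field(grid(span=40_000.0, dx=1_000.0, hours=60), omega)
        c2 = rotation_field(grid(span=40_000.0, dx=1_000.0, hours=60), omega)
        tiny = rotation_field(grid(span=100.0, dx=50.0, hours=60), omega)
        s_nested = nested(f, c)
        s_single = NestedVelocitySampler(fine=tiny, coarse=c2)
        parts = lambda: [ParticleState(0, "A", x=8_000.0, y=0.0, z=1.0, release_time=0.0)]
        cfg = TrackerConfig(duration_days=1.0, mode="depthavg2d")
        ta = track(parts(), s_nested, cfg)[0]
        tb = track(parts(), s_single, cfg)[0]
        # the orbit (radius 8 km) dips inside the 5 km fine box near the axes
        assert np.hypot(ta.x - tb.x, ta.y - tb.y).max() < 1.0

    def test_vertical_reflection_at_surface_and_seabed(self):
        g = grid(span=10_000.0, dx=500.0, layers=(0.0, 2.0, 10.0))
        cg = grid(span=40_000.0, dx=2_000.0, layers=(0.0, 2.0, 10.0))
        up = np.full((g.time_points.size, 2, g.y_coords.size, g.x_coords.size), 0.0)
        w = np.full_like(up, 0.01)  # downward 0.01 m/s
        f = VelocityFieldSet(grid=g, u=up, v=up.copy(), w=w, mode=FULL_3D)
        c = uniform_field(cg, mode=FULL_3D)
        bathy = BathymetryField(
            grid=g, depth=np.full((g.y_coords.size, g.x_coords.size), 8.0)
        )
        s = NestedVelocitySampler(fine=f, coarse=c, bathymetry=bathy)
        cfg = TrackerConfig(duration_days=0.5, mode="full3d")
        tr = track([ParticleState(0, "A", 0.0, 0.0, 2.0, 0.0)], s, cfg)[0]
        assert np.all(tr.z >= 0.0)
        assert np.all(tr.z <= 8.0 + 1e-9)
        assert tr.z.max() > 6.0  # actually sank and reflected

    def test_accounting_identity(self):
        trajs = [
            Trajectory(0, "A", np.array([]), np.array([]), np.array([]), np.array([]), "exited"),
            Trajectory(1, "A", np.array([0.25]), np.zeros(1), np.zeros(1), np.zeros(1), "settled", "A"),
            Trajectory(2, "A", np.array([0.25]), np.zeros(1), np.zeros(1), np.zeros(1), "active"),
        ]
        counts = accounting(trajs)
        assert counts["released"] == 3
        assert counts["exited"] == counts["settled"] == counts["active"] == 1

    def test_netcdf_export(self, tmp_path):
        f = uniform_field(grid(span=10_000.0, dx=500.0), u=-0.1)
        c = uniform_field(grid(span=40_000.0, dx=2_000.0), u=-0.1)
        cfg = TrackerConfig(duration_days=0.5, mode="depthavg2d")
        trajs = track(self._particles(3), nested(f, c), cfg)
        p = tmp_path / "traj.nc"
        trajectories_to_netcdf(trajs, p)
        import xarray as xr

        with xr.open_dataset(p, engine="scipy") as ds:
            assert ds.sizes["particle"] == 3
            assert ds["x"].shape[1] == trajs[0].times.size


class TestTrackerConfig:
    def test_record_must_divide(self):
        with pytest.raises(ValueError, match="multiple"):
            TrackerConfig(step_minutes=5.0, record_interval_minutes=7.0)

    def test_defaults_follow_protocol(self):
        cfg = TrackerConfig()
        assert cfg.step_minutes == 5.0
        assert cfg.record_interval_minutes == 15.0
        assert cfg.duration_days == 30.0
        assert cfg.steps_per_record == 3
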