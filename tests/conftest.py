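"""Shared fixtures: small analytic grids, fields and site sets."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from reefconnect.habitat_polygons import SitePolygon
from reefconnect.synthetic_environment import (
    FULL_3D,
    GridSpec,
    VelocityFieldSet,
)


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(
        x_coords=np.arange(-5_000.0, 5_001.0, 500.0),
        y_coords=np.arange(-5_000.0, 5_001.0, 500.0),
        layer_interfaces=np.array([0.0, 1.0, 5.0, 20.0]),
        time_points=np.arange(0.0, 49.0),
    )


@pytest.fixture
def single_layer_grid() -> GridSpec:
    return GridSpec(
        x_coords=np.arange(-5_000.0, 5_001.0, 500.0),
        y_coords=np.arange(-5_000.0, 5_001.0, 500.0),
        layer_interfaces=np.array([0.0, 5.0]),
        time_points=np.arange(0.0, 49.0),
    )


def rotation_field(
    grid: GridSpec, omega_per_hour: float, centre=(0.0, 0.0)
) -> VelocityFieldSet:
    """Solid-body rotation u = -w(y-yc), v = w(x-xc); w in rad/s.

    Linear in space, constant in time, so multilinear interpolation is
    exact and trajectory errors are purely the integrator's.
    """
    omega = omega_per_hour / 3600.0
    X, Y = np.meshgrid(grid.x_coords, grid.y_coords)
    nt, nk = grid.time_points.size, grid.n_layers
    u = np.broadcast_to(-omega * (Y - centre[1]), (nt, nk) + X.shape).copy()
    v = np.broadcast_to(omega * (X - centre[0]), (nt, nk) + X.shape).copy()
    mode = FULL_3D if nk > 1 else "depthavg2d"
    if nk > 1:
        return VelocityFieldSet(grid=grid, u=u, v=v, w=np.zeros_like(u), mode=mode)
    return VelocityFieldSet(grid=grid, u=u, v=v, mode=mode)


def square_sites(n: int, size: float = 500.0, spacing: float = 2_000.0) -> list[SitePolygon]:
    """n square site polygons along the x axis (test stand-ins)."""
    sites = []
    for i in range(n):
        cx = -i * spacing
        geom = box(cx - size / 2, -size / 2, cx + size / 2, size / 2)
        sites.append(
            SitePolygon(
                site_id=f"S{i:03d}",
                zone="ReefCrest",
                members=[i],
                geometry=geom,
                area=float(geom.area),
                centroid=(cx, 0.0),
            )
        )
    return sites
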