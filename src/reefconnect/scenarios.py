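"""Canned synthetic study scenarios for the connectivity pipeline.

Two scenarios capture the qualitative flow regimes the analysis is
sensitive to:

``westward_drift``
    A reef-site transect under a mean offshore-to-onshore (east-to-west)
    drift with a superimposed along-drift tidal oscillation and mild
    vertical shear.  Larvae released at eastern sites are carried over
    western sites during their competency window, so the network's
    consistent sinks sit downstream (west) of its consistent sources.

``shear_retention``
    Strongly sheared flow: the thin surface layer exports larvae offshore
    and out of the outer domain before they become competent, while
    sub-surface layers only oscillate with the tide and retain larvae
    over their natal reef.  Trajectories forced with surface-only 2-D
    velocities therefore produce far fewer links and sink sites than
    full-3-D trajectories at the release depth.

Both scenarios build a fine inner grid nested in a coarse outer grid that
encode the same analytic flow, reef-platform bathymetry beneath each
site, and a hexagon transect regionalized into one site polygon per reef
patch.  Numbers follow the study protocol where it states them (release
cadence and depth, competency, mortality); domain sizes and flow
magnitudes are scaled-down but realistic shelf values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .habitat_polygons import SitePolygon, regionalize
from .synthetic_environment import (
    BathymetryField,
    GridSpec,
    HexagonMap,
    VelocityFieldSet,
    make_drift_tide_field,
    make_hexagon_map,
    make_reef_bathymetry,
)

M2_TIDAL_PERIOD_H = 12.42

# pointy-top hexagons 200 m across -> 19-hexagon patches about 1 km wide
TRANSECT_HEX_AREA = float(np.sqrt(3.0) / 2.0 * 200.0**2)
TRANSECT_PATCH_RINGS = 2
TRANSECT_SPACING_M = 3_000.0


@dataclass
class ScenarioBundle:
    """Everything a pipeline run needs: fields, bathymetry and sites."""

    name: str
    fine3d: VelocityFieldSet
    coarse3d: VelocityFieldSet
    fine_bathymetry: BathymetryField
    coarse_bathymetry: BathymetryField
    hex_map: HexagonMap
    sites: list[SitePolygon]


def site_transect_map(
    n_sites: int = 7,
    spacing: float = TRANSECT_SPACING_M,
    seed: int = 0,
    zone: str = "ReefCrest",
) -> HexagonMap:
    """Hexagon patches of one geomorphic zone along an east-west transect.

    Patch ``i`` sits at x = -i * spacing with a distinct characteristic
    depth (2 + 2 i m, jittered), so the depth-homogeneity partition of
    the zone's spanning tree recovers one site per patch.
    """
    patches = []
    offset = 0
    n_per_patch = 1 + 3 * TRANSECT_PATCH_RINGS * (TRANSECT_PATCH_RINGS + 1)
    for i in range(n_sites):
        patch = make_hexagon_map(
            n_rings=TRANSECT_PATCH_RINGS,
            hex_area=TRANSECT_HEX_AREA,
            zone_rule=lambda ring: zone,
            depth_rule=lambda dist, base=2.0 + 2.0 * i: base,
            seed=seed + i,
            centre=(-i * spacing, 0.0),
            depth_jitter=0.15,
            id_offset=offset,
        )
        offset += n_per_patch
        patches.append(patch)
    return HexagonMap.merge(patches)


def transect_sites(hex_map: HexagonMap) -> list[SitePolygon]:
    """Regionalize the transect: one site polygon per reef patch."""
    n_patch = 1 + 3 * TRANSECT_PATCH_RINGS * (TRANSECT_PATCH_RINGS + 1)
    return regionalize(
        hex_map,
        min_size=n_patch,
        target_area=n_patch * TRANSECT_HEX_AREA,
    )


def _grids(n_sites: int, spacing: float, duration_hours: float,
           layer_interfaces: np.ndarray) -> tuple[GridSpec, GridSpec]:
    west = -(n_sites - 1) * spacing
    times = np.arange(0.0, duration_hours + 1.0)
    fine = GridSpec(
        x_coords=np.arange(west - 5_000.0, 3_000.0 + 1, 500.0),
        y_coords=np.arange(-3_000.0, 3_000.0 + 1, 500.0),
        layer_interfaces=layer_interfaces,
        time_points=times,
    )
    coarse = GridSpec(
        x_coords=np.arange(west - 45_000.0, 31_000.0 + 1, 2_000.0),
        y_coords=np.arange(-21_000.0, 21_000.0 + 1, 2_000.0),
        layer_interfaces=layer_interfaces,
        time_points=times,
    )
    return fine, coarse


def _platforms(sites: list[SitePolygon]) -> list[tuple[tuple[float, float], float, float]]:
    return [((s.centroid[0], s.centroid[1]), 800.0, 3.0) for s in sites]


def westward_drift_scenario(
    n_sites: int = 7,
    seed: int = 0,
    duration_hours: float = 336.0,
    mean_u: float = -0.025,
    tidal_amp: float = 0.15,
) -> ScenarioBundle:
    """Mean westward drift + tide over a reef-site transect.

    Layer interfaces put the 2.25 m release depth exactly at the middle
    layer's midpoint; shear decays with depth so the three velocity modes
    genuinely differ.  The along-drift (u) tide dominates; the cross-
    drift (v) tide is weak so larvae stay within the transect corridor.
    """
    interfaces = np.array([0.0, 0.5, 4.0, 30.0])
    hex_map = site_transect_map(n_sites=n_sites, seed=seed)
    sites = transect_sites(hex_map)
    fine_grid, coarse_grid = _grids(
        n_sites, TRANSECT_SPACING_M, duration_hours, interfaces
    )
    shear = [1.0, 0.8, 0.5]
    kwargs = dict(
        mean_u=mean_u,
        mean_v=0.0,
        tidal_amp=tidal_amp,
        tidal_period=M2_TIDAL_PERIOD_H,
        shear=shear,
        tidal_amp_v=0.02,
    )
    fine_bathy = make_reef_bathymetry(fine_grid, _platforms(sites), background_depth=35.0)
    coarse_bathy = make_reef_bathymetry(coarse_grid, _platforms(sites), background_depth=35.0)
    return ScenarioBundle(
        name="westward_drift",
        fine3d=make_drift_tide_field(fine_grid, seed=seed, **kwargs),
        coarse3d=make_drift_tide_field(coarse_grid, seed=seed, **kwargs),
        fine_bathymetry=fine_bathy,
        coarse_bathymetry=coarse_bathy,
        hex_map=hex_map,
        sites=sites,
    )


def shear_retention_scenario(
    n_sites: int = 7,
    seed: int = 0,
    duration_hours: float = 192.0,
    surface_export_u: float = -0.25,
    subsurface_tidal_amp: float = 0.1,
) -> ScenarioBundle:
    """Surface export over sub-surface tidal retention.

    The surface layer carries a strong steady offshore current that
    removes larvae from the outer domain before competency opens; deeper
    layers carry only a zero-mean tidal oscillation that keeps larvae
    over their natal reef, where they self-recruit once competent.
    """
    interfaces = np.array([0.0, 0.5, 4.0, 30.0])
    hex_map = site_transect_map(n_sites=n_sites, seed=seed)
    sites = transect_sites(hex_map)
    fine_grid, coarse_grid = _grids(
        n_sites, TRANSECT_SPACING_M, duration_hours, interfaces
    )

    def build(grid: GridSpec) -> VelocityFieldSet:
        export = make_drift_tide_field(
            grid, mean_u=surface_export_u, mean_v=0.0, tidal_amp=0.0,
            tidal_period=M2_TIDAL_PERIOD_H, shear=[1.0, 0.0, 0.0], seed=seed,
        )
        tide = make_drift_tide_field(
            grid, mean_u=0.0, mean_v=0.0, tidal_amp=subsurface_tidal_amp,
            tidal_period=M2_TIDAL_PERIOD_H, shear=[0.0, 1.0, 1.0],
            tidal_amp_v=0.0, seed=seed,
        )
        return superpose(export, tide)

    fine_bathy = make_reef_bathymetry(fine_grid, _platforms(sites), background_depth=35.0)
    coarse_bathy = make_reef_bathymetry(coarse_grid, _platforms(sites), background_depth=35.0)
    return ScenarioBundle(
        name="shear_retention",
        fine3d=build(fine_grid),
        coarse3d=build(coarse_grid),
        fine_bathymetry=fine_bathy,
        coarse_bathymetry=coarse_bathy,
        hex_map=hex_map,
        sites=sites,
    )


def superpose(a: VelocityFieldSet, b: VelocityFieldSet) -> VelocityFieldSet:
    """Sum two velocity fields defined on the same grid and mode."""
    if a.mode != b.mode or a.grid.shape != b.grid.shape:
        raise ValueError("fields must share grid shape and mode")
    w = None
    if a.w is not None:
        w = a.w + b.w
    return VelocityFieldSet(
        grid=a.grid, u=a.u + b.u, v=a.v + b.v, w=w, mode=a.mode,
        land_mask=a.land_mask | b.land_mask,
    )


SCENARIOS = {
    "westward_drift": westward_drift_scenario,
    "shear_retention": shear_retention_scenario,
}
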