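"""Analytic velocity fields, bathymetry and hexagonal habitat maps.

Downstream stages of the connectivity pipeline (regionalization, particle
tracking, settlement, network analysis) are exercised on synthetic inputs
that carry the statistical structure the analysis assumes: a mean
offshore-to-onshore drift with a superimposed tidal oscillation, vertical
shear so that surface, depth-averaged and fully three-dimensional
trajectories differ, reef platforms rising from a deeper shelf, and
hexagonal habitat lattices partitioned into geomorphic zones with a depth
gradient.

Grids are rectilinear with hourly velocity snapshots.  Land is defined as
bathymetry <= 0 and velocities are identically zero on land cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import xarray as xr

HABITAT_ZONES = ("ReefSlope", "ReefCrest", "ShelteredSlope", "OuterReefFlat")

SURFACE_2D = "surface2d"
DEPTH_AVG_2D = "depthavg2d"
FULL_3D = "full3d"
MODES = (SURFACE_2D, DEPTH_AVG_2D, FULL_3D)


def _check_axis(name: str, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 1 or coords.size < 2:
        raise ValueError(f"{name} must be 1-D with at least two points")
    steps = np.diff(coords)
    if np.any(steps <= 0):
        raise ValueError(f"{name} must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise ValueError(f"{name} must be uniformly spaced")
    return coords


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear space/time grid for a velocity field.

    ``layer_interfaces`` are metres below the surface, ascending, starting
    at 0; a field with ``n`` layers has ``n + 1`` interfaces.  Times are
    hours since the start of the scenario.
    """

    x_coords: np.ndarray
    y_coords: np.ndarray
    layer_interfaces: np.ndarray
    time_points: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_coords", _check_axis("x_coords", self.x_coords))
        object.__setattr__(self, "y_coords", _check_axis("y_coords", self.y_coords))
        object.__setattr__(self, "time_points", _check_axis("time_points", self.time_points))
        ifaces = np.asarray(self.layer_interfaces, dtype=float)
        if ifaces.ndim != 1 or ifaces.size < 2:
            raise ValueError("layer_interfaces needs at least two values")
        if ifaces[0] != 0.0:
            raise ValueError("first layer interface must be 0 (the surface)")
        if np.any(np.diff(ifaces) <= 0):
            raise ValueError("layer thicknesses must be strictly positive")
        object.__setattr__(self, "layer_interfaces", ifaces)

    @property
    def n_layers(self) -> int:
        return self.layer_interfaces.size - 1

    @property
    def layer_midpoints(self) -> np.ndarray:
        i = self.layer_interfaces
        return 0.5 * (i[:-1] + i[1:])

    @property
    def layer_thickness(self) -> np.ndarray:
        return np.diff(self.layer_interfaces)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (
            self.time_points.size,
            self.n_layers,
            self.y_coords.size,
            self.x_coords.size,
        )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid."""
        return (
            float(self.x_coords[0]),
            float(self.x_coords[-1]),
            float(self.y_coords[0]),
            float(self.y_coords[-1]),
        )


@dataclass
class BathymetryField:
    """Water depth in metres, positive down, on a grid's (y, x) plane."""

    grid: GridSpec
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        expected = (self.grid.y_coords.size, self.grid.x_coords.size)
        if self.depth.shape != expected:
            raise ValueError(f"depth shape {self.depth.shape} != grid plane {expected}")

    @property
    def land_mask(self) -> np.ndarray:
        return self.depth <= 0.0


@dataclass
class VelocityFieldSet:
    """Gridded hourly velocities (u east, v north, w down-positive-z absent in 2D).

    Arrays are (time, layer, y, x).  ``mode`` distinguishes surface-only,
    depth-averaged and full 3-D fields; the 2-D modes carry exactly one
    layer and no ``w``.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    mode: str
    w: np.ndarray | None = None
    land_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.grid.shape or self.v.shape != self.grid.shape:
            raise ValueError("u/v shape must match grid (time, layer, y, x)")
        if self.mode in (SURFACE_2D, DEPTH_AVG_2D):
            if self.grid.n_layers != 1:
                raise ValueError(f"{self.mode} fields must have exactly one layer")
            if self.w is not None:
                raise ValueError("2-D fields carry no vertical velocity")
        else:
            if self.w is None:
                self.w = np.zeros_like(self.u)
            else:
                self.w = np.asarray(self.w, dtype=float)
                if self.w.shape != self.grid.shape:
                    raise ValueError("w shape must match grid")
        if self.land_mask is None:
            ny, nx = self.grid.y_coords.size, self.grid.x_coords.size
            self.land_mask = np.zeros((ny, nx), dtype=bool)
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("velocities must be finite")
        if np.any(self.land_mask):
            for comp in (self.u, self.v) + ((self.w,) if self.w is not None else ()):
                if np.any(comp[:, :, self.land_mask] != 0.0):
                    raise ValueError("velocities must be exactly zero on land cells")

    def to_netcdf(self, path: str | Path) -> None:
        """Write as CF-style NetCDF (scipy backend, NETCDF3)."""
        g = self.grid
        data = {
            "u": (("time", "depth", "y", "x"), self.u, {"units": "m s-1"}),
            "v": (("time", "depth", "y", "x"), self.v, {"units": "m s-1"}),
            "mask": (("y", "x"), self.land_mask.astype("int8")),
        }
        if self.w is not None:
            data["w"] = (("time", "depth", "y", "x"), self.w, {"units": "m s-1"})
        ds = xr.Dataset(
            data,
            coords={
                "time": ("time", g.time_points, {"units": "hours"}),
                "depth": ("depth", g.layer_midpoints, {"units": "m", "positive": "down"}),
                "y": ("y", g.y_coords, {"units": "m"}),
                "x": ("x", g.x_coords, {"units": "m"}),
            },
            attrs={
                "velocity_mode": self.mode,
                "layer_interfaces": " ".join(repr(float(v)) for v in g.layer_interfaces),
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "VelocityFieldSet":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
        grid = GridSpec(
            x_coords=ds["x"].values,
            y_coords=ds["y"].values,
            layer_interfaces=np.array([float(s) for s in ds.attrs["layer_interfaces"].split()]),
            time_points=ds["time"].values,
        )
        return cls(
            grid=grid,
            u=ds["u"].values,
            v=ds["v"].values,
            w=ds["w"].values if "w" in ds else None,
            mode=ds.attrs["velocity_mode"],
            land_mask=ds["mask"].values.astype(bool),
        )


@dataclass(frozen=True)
class Hexagon:
    hex_id: int
    centroid: tuple[float, float]
    vertices: tuple[tuple[float, float], ...]
    zone: str
    depth: float
    area: float


@dataclass
class HexagonMap:
    """Equal-area hexagonal habitat lattice with geomorphic-zone labels."""

    hexagons: list[Hexagon]

    def __post_init__(self) -> None:
        ids = [h.hex_id for h in self.hexagons]
        if len(ids) != len(set(ids)):
            raise ValueError("hexagon ids must be unique")
        areas = {round(h.area, 6) for h in self.hexagons}
        if len(areas) > 1:
            raise ValueError("all hexagons in one map must have equal area")
        bad = {h.zone for h in self.hexagons} - set(HABITAT_ZONES)
        if bad:
            raise ValueError(f"unknown habitat zones: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.hexagons)

    @property
    def hex_area(self) -> float:
        return self.hexagons[0].area if self.hexagons else 0.0

    @property
    def total_area(self) -> float:
        return sum(h.area for h in self.hexagons)

    def zone_subset(self, zone: str) -> list[Hexagon]:
        return [h for h in self.hexagons if h.zone == zone]

    def translated(self, dx: float, dy: float, id_offset: int = 0) -> "HexagonMap":
        """Copy of the map shifted in space (ids offset to stay unique)."""
        moved = [
            Hexagon(
                hex_id=h.hex_id + id_offset,
                centroid=(h.centroid[0] + dx, h.centroid[1] + dy),
                vertices=tuple((vx + dx, vy + dy) for vx, vy in h.vertices),
                zone=h.zone,
                depth=h.depth,
                area=h.area,
            )
            for h in self.hexagons
        ]
        return HexagonMap(moved)

    @staticmethod
    def merge(maps: Sequence["HexagonMap"]) -> "HexagonMap":
        out: list[Hexagon] = []
        for m in maps:
            out.extend(m.hexagons)
        return HexagonMap(out)

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for h in self.hexagons:
            ring = list(h.vertices) + [h.vertices[0]]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "id": h.hex_id,
                        "zone": h.zone,
                        "depth": h.depth,
                        "area": h.area,
                    },
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "HexagonMap":
        fc = json.loads(Path(path).read_text())
        hexes = []
        for feat in fc["features"]:
            ring = feat["geometry"]["coordinates"][0]
            verts = tuple((float(x), float(y)) for x, y in ring[:-1])
            cx = sum(v[0] for v in verts) / len(verts)
            cy = sum(v[1] for v in verts) / len(verts)
            p = feat["properties"]
            hexes.append(
                Hexagon(
                    hex_id=int(p["id"]),
                    centroid=(cx, cy),
                    vertices=verts,
                    zone=p["zone"],
                    depth=float(p["depth"]),
                    area=float(p["area"]),
                )
            )
        return cls(hexes)


# ---------------------------------------------------------------------------
# Field generators


def make_drift_tide_field(
    grid: GridSpec,
    mean_u: float,
    mean_v: float,
    tidal_amp: float,
    tidal_period: float,
    shear: Sequence[float],
    seed: int = 0,
    bathymetry: BathymetryField | None = None,
    mode: str | None = None,
    tidal_amp_v: float | None = None,
) -> VelocityFieldSet:
    """Mean drift plus sinusoidal tide, modulated per layer by ``shear``.

    u(t, k) = shear[k] * (mean_u + tidal_amp * sin(2 pi t / tidal_period))
    and analogously for v; w = 0.  By default the tidal amplitude is the
    same in both components; ``tidal_amp_v`` overrides the north
    component to model an anisotropic tidal ellipse.  The time average
    over whole tidal periods is the sheared mean drift.  Deterministic
    given its arguments (``seed`` is accepted for interface symmetry with
    the other generators but unused: the field has no stochastic
    component).
    """
    if tidal_period <= 0:
        raise ValueError("tidal_period must be positive")
    shear = np.asarray(shear, dtype=float)
    if shear.size != grid.n_layers:
        raise ValueError(
            f"shear needs one multiplier per layer ({grid.n_layers}), got {shear.size}"
        )
    t = grid.time_points
    tide = np.sin(2.0 * np.pi * t / tidal_period)  # (time,)
    amp_v = tidal_amp if tidal_amp_v is None else tidal_amp_v
    base_u = mean_u + tidal_amp * tide
    base_v = mean_v + amp_v * tide
    nt, nk = t.size, grid.n_layers
    ny, nx = grid.y_coords.size, grid.x_coords.size
    u = (base_u[:, None] * shear[None, :])[:, :, None, None] * np.ones((1, 1, ny, nx))
    v = (base_v[:, None] * shear[None, :])[:, :, None, None] * np.ones((1, 1, ny, nx))
    w = np.zeros((nt, nk, ny, nx))
    land = None
    if bathymetry is not None:
        land = bathymetry.land_mask
        u[:, :, land] = 0.0
        v[:, :, land] = 0.0
    if mode is None:
        mode = FULL_3D if nk > 1 else DEPTH_AVG_2D
    if mode in (SURFACE_2D, DEPTH_AVG_2D):
        return VelocityFieldSet(grid=grid, u=u, v=v, mode=mode, land_mask=land)
    return VelocityFieldSet(grid=grid, u=u, v=v, w=w, mode=mode, land_mask=land)


def make_reef_bathymetry(
    grid: GridSpec,
    platforms: Sequence[tuple[tuple[float, float], float, float]],
    background_depth: float,
    ramp_width: float | None = None,
) -> BathymetryField:
    """Reef platforms in a flat shelf.

    Each platform is ((cx, cy), radius, crest_depth): depth equals
    ``crest_depth`` within ``radius`` of the centre and rises smoothly
    (half-cosine over ``ramp_width``, default one radius) to
    ``background_depth`` outside.  Overlapping platforms take the minimum
    depth.
    """
    for (_, radius, crest) in platforms:
        if radius <= 0:
            raise ValueError("platform radius must be positive")
        if crest >= background_depth:
            raise ValueError("crest_depth must be shallower than background_depth")
    X, Y = np.meshgrid(grid.x_coords, grid.y_coords)
    depth = np.full(X.shape, float(background_depth))
    for (cx, cy), radius, crest in platforms:
        ramp = ramp_width if ramp_width is not None else radius
        r = np.hypot(X - cx, Y - cy)
        frac = np.clip((r - radius) / ramp, 0.0, 1.0)
        profile = crest + (background_depth - crest) * 0.5 * (1 - np.cos(np.pi * frac))
        depth = np.minimum(depth, profile)
    return BathymetryField(grid=grid, depth=depth)


def _hex_vertices(cx: float, cy: float, side: float) -> tuple[tuple[float, float], ...]:
    """Pointy-top hexagon vertex ring around (cx, cy)."""
    angles = np.deg2rad(np.arange(30, 390, 60))
    return tuple((cx + side * np.cos(a), cy + side * np.sin(a)) for a in angles)


def default_zone_rule(ring: int) -> str:
    """Radial zone bands cycling through the four zones.

    Cycling by ring index deliberately makes each zone a set of separated
    annuli, exercising spatially non-contiguous zone membership.
    """
    return HABITAT_ZONES[ring % 4]


def make_hexagon_map(
    n_rings: int,
    hex_area: float,
    zone_rule: Callable[[int], str] | None = None,
    depth_rule: Callable[[float], float] | None = None,
    seed: int = 0,
    centre: tuple[float, float] = (0.0, 0.0),
    depth_jitter: float = 0.2,
    id_offset: int = 0,
) -> HexagonMap:
    """Hexagonal lattice of ``1 + 3 n (n+1)`` equal-area hexagons.

    ``zone_rule`` maps ring index to a habitat zone (default: cycle through
    the four zones).  ``depth_rule`` maps distance from the lattice centre
    (the reef crest) to depth in metres; the default is a gentle monotone
    deepening from 1 m, with a small seeded jitter so depths are not
    exactly degenerate.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if hex_area <= 0:
        raise ValueError("hex_area must be positive")
    zone_rule = zone_rule or default_zone_rule
    side = np.sqrt(2.0 * hex_area / (3.0 * np.sqrt(3.0)))
    width = np.sqrt(3.0) * side  # flat-to-flat distance, pointy-top
    rng = np.random.default_rng(seed)
    if depth_rule is None:
        scale = width * n_rings

        def depth_rule(d: float) -> float:
            return 1.0 + 8.0 * d / max(scale, 1e-9)

    # axial coordinates; pointy-top: x = w*(q + r/2), y = 1.5*side*r
    cells: list[tuple[int, int, int]] = [(0, 0, 0)]
    for ring in range(1, n_rings + 1):
        q, r = ring, 0
        directions = [(-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)]
        for dq, dr in directions:
            for _ in range(ring):
                cells.append((q, r, ring))
                q, r = q + dq, r + dr
    hexes = []
    cx0, cy0 = centre
    for i, (q, r, ring) in enumerate(cells):
        cx = cx0 + width * (q + r / 2.0)
        cy = cy0 + 1.5 * side * r
        dist = float(np.hypot(cx - cx0, cy - cy0))
        depth = float(depth_rule(dist)) + float(rng.normal(0.0, depth_jitter))
        depth = max(depth, 0.1)
        hexes.append(
            Hexagon(
                hex_id=id_offset + i,
                centroid=(cx, cy),
                vertices=_hex_vertices(cx, cy, side),
                zone=zone_rule(ring),
                depth=depth,
                area=float(hex_area),
            )
        )
    expected = 1 + 3 * n_rings * (n_rings + 1)
    assert len(hexes) == expected
    return HexagonMap(hexes)


def make_solid_body_rotation_field(
    grid: GridSpec, omega_per_hour: float, centre: tuple[float, float] = (0.0, 0.0)
) -> VelocityFieldSet:
    """Solid-body rotation u = -omega (y - yc), v = omega (x - xc).

    Linear in space and constant in time, so multilinear sampling
    reproduces it exactly; trajectories are analytic circles, which makes
    this the reference flow for integrator accuracy checks.
    """
    omega = omega_per_hour / 3600.0
    X, Y = np.meshgrid(grid.x_coords, grid.y_coords)
    nt, nk = grid.time_points.size, grid.n_layers
    u = np.broadcast_to(-omega * (Y - centre[1]), (nt, nk) + X.shape).copy()
    v = np.broadcast_to(omega * (X - centre[0]), (nt, nk) + X.shape).copy()
    if nk > 1:
        return VelocityFieldSet(grid=grid, u=u, v=v, w=np.zeros_like(u), mode=FULL_3D)
    return VelocityFieldSet(grid=grid, u=u, v=v, mode=DEPTH_AVG_2D)


# ---------------------------------------------------------------------------
# Dimensional reductions


def derive_surface(field3d: VelocityFieldSet) -> VelocityFieldSet:
    """Extract the surface layer of a 3-D field as a single-layer 2-D field."""
    if field3d.mode != FULL_3D:
        raise ValueError("derive_surface requires a full3d field")
    g = field3d.grid
    grid2d = GridSpec(
        x_coords=g.x_coords,
        y_coords=g.y_coords,
        layer_interfaces=g.layer_interfaces[:2],
        time_points=g.time_points,
    )
    return VelocityFieldSet(
        grid=grid2d,
        u=field3d.u[:, :1].copy(),
        v=field3d.v[:, :1].copy(),
        mode=SURFACE_2D,
        land_mask=field3d.land_mask.copy(),
    )


def derive_depth_averaged(
    field3d: VelocityFieldSet, bathy: BathymetryField
) -> VelocityFieldSet:
    """Thickness-weighted vertical mean of a 3-D field above the local seabed.

    Layer thicknesses are clipped to the local water depth; a zero water
    column is treated as land (velocity zero).
    """
    if field3d.mode != FULL_3D:
        raise ValueError("derive_depth_averaged requires a full3d field")
    g = field3d.grid
    if bathy.depth.shape != (g.y_coords.size, g.x_coords.size):
        raise ValueError("bathymetry grid plane must match the velocity grid")
    tops = g.layer_interfaces[:-1]
    bots = g.layer_interfaces[1:]
    depth = bathy.depth  # (y, x)
    # effective thickness of each layer at each column, clipped to seabed
    eff = np.clip(depth[None, :, :] - tops[:, None, None], 0.0, None)
    eff = np.minimum(eff, (bots - tops)[:, None, None])  # (layer, y, x)
    total = eff.sum(axis=0)  # (y, x)
    wet = total > 0.0
    weights = np.where(wet[None], eff / np.where(total[None] == 0, 1.0, total[None]), 0.0)
    u_avg = np.einsum("tkyx,kyx->tyx", field3d.u, weights)[:, None]
    v_avg = np.einsum("tkyx,kyx->tyx", field3d.v, weights)[:, None]
    land = ~wet | bathy.land_mask
    u_avg[:, :, land] = 0.0
    v_avg[:, :, land] = 0.0
    grid2d = GridSpec(
        x_coords=g.x_coords,
        y_coords=g.y_coords,
        layer_interfaces=np.array([0.0, g.layer_interfaces[-1]]),
        time_points=g.time_points,
    )
    return VelocityFieldSet(
        grid=grid2d, u=u_avg, v=v_avg, mode=DEPTH_AVG_2D, land_mask=land
    )
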