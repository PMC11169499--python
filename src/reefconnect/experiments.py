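"""Reusable numerical experiments on the synthetic study scenarios.

These are the package's headline computations, shared by the test suite,
the examples and the reproduction script:

* integrator accuracy on the analytic solid-body-rotation orbit;
* recovery of the flow's downstream direction from the consistency
  classification (sinks downstream of sources under a mean drift);
* sensitivity of network size (links, sink sites) to the dimensionality
  of the velocity fields (surface-2D versus full-3D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, consistency, count_links, pct_settled
from .particle_tracker import NestedVelocitySampler, _rk4_core
from .pipeline import RunConfig, run_night
from .scenarios import shear_retention_scenario, westward_drift_scenario
from .synthetic_environment import (
    DEPTH_AVG_2D,
    GridSpec,
    make_solid_body_rotation_field,
)


# ---------------------------------------------------------------------------
# Integrator accuracy


def rotation_sampler(omega_per_hour: float = 2 * np.pi / 12.0) -> NestedVelocitySampler:
    def grid(span, dx):
        return GridSpec(
            x_coords=np.arange(-span, span + 1, dx),
            y_coords=np.arange(-span, span + 1, dx),
            layer_interfaces=np.array([0.0, 5.0]),
            time_points=np.arange(0.0, 61.0),
        )

    fine = make_solid_body_rotation_field(grid(10_000.0, 500.0), omega_per_hour)
    coarse = make_solid_body_rotation_field(grid(40_000.0, 2_000.0), omega_per_hour)
    return NestedVelocitySampler(fine=fine, coarse=coarse)


def orbit_closure_error(
    sampler: NestedVelocitySampler,
    dt_minutes: float,
    radius: float = 3_000.0,
    period_hours: float = 12.0,
) -> float:
    """Distance from the start point after one full analytic revolution."""
    n = int(round(period_hours * 60.0 / dt_minutes))
    x, y, z = np.array([radius]), np.array([0.0]), np.array([1.0])
    for k in range(n):
        t = np.array([k * dt_minutes / 60.0])
        x, y, z, exited = _rk4_core(sampler, x, y, z, t, dt_minutes * 60.0, DEPTH_AVG_2D)
        if exited[0]:
            raise RuntimeError("orbit left the domain")
    return float(np.hypot(x[0] - radius, y[0]))


def rk4_convergence_ratios(dt_minutes: tuple[float, ...] = (30.0, 15.0, 7.5, 3.75)):
    """Orbit-closure errors and their ratios under successive dt halving.

    Classical RK4 is fourth order: halving dt divides the error by ~16.
    """
    sampler = rotation_sampler()
    errors = [orbit_closure_error(sampler, dt) for dt in dt_minutes]
    ratios = [e0 / e1 for e0, e1 in zip(errors, errors[1:])]
    return errors, ratios


# ---------------------------------------------------------------------------
# Directional recovery


@dataclass
class DirectionalResult:
    matrices: list[ConnectivityMatrix]
    source_mean_x: float
    sink_mean_x: float
    n_consistent_sources: int
    n_consistent_sinks: int

    @property
    def sinks_downstream(self) -> bool:
        """True when consistent sinks sit strictly west of consistent sources."""
        return self.sink_mean_x < self.source_mean_x


def directional_recovery_trial(
    seed: int,
    n_sites: int = 7,
    n_nights: int = 3,
    duration_days: float = 10.0,
    mortality_rate: float | None = 0.40,
) -> DirectionalResult:
    """One seeded replicate of the westward-drift consistency experiment.

    Releases the full per-night cohort (61 larvae per site) on each of
    ``n_nights`` consecutive nights, tracks with 3-D velocities, applies
    daily mortality and settlement, and classifies consistent sources and
    sinks over the nights.  Returns the released-weighted mean centroid
    abscissa of each class (releases are equal across sites, so this is
    the plain mean).
    """
    nights = [24.0 * k for k in range(n_nights)]
    horizon = nights[-1] + 24.0 + duration_days * 24.0
    bundle = westward_drift_scenario(
        n_sites=n_sites, seed=seed, duration_hours=float(np.ceil(horizon)) + 1.0
    )
    config = RunConfig(
        out_dir="unused",
        nights=nights,
        modes=["full3d"],
        duration_days=duration_days,
        mortality_rate=mortality_rate,
        master_seed=seed,
    )
    matrices = []
    for k, night_start in enumerate(nights):
        matrix, _, _, _, _ = run_night(bundle, "full3d", night_start, f"night-{k}", config)
        matrices.append(matrix)
    report = consistency(matrices)
    xs = {s.site_id: s.centroid[0] for s in bundle.sites}
    src = [xs[s] for s, f in zip(report["site_id"], report["consistent_source"]) if f]
    snk = [xs[s] for s, f in zip(report["site_id"], report["consistent_sink"]) if f]
    return DirectionalResult(
        matrices=matrices,
        source_mean_x=float(np.mean(src)) if src else np.nan,
        sink_mean_x=float(np.mean(snk)) if snk else np.nan,
        n_consistent_sources=len(src),
        n_consistent_sinks=len(snk),
    )


# ---------------------------------------------------------------------------
# Velocity-dimension sensitivity


@dataclass
class SensitivityResult:
    links_full3d: int
    links_surface2d: int
    sinks_full3d: int
    sinks_surface2d: int
    pct_settled_full3d: float
    pct_settled_surface2d: float

    @property
    def pct_more_links(self) -> float | None:
        if self.links_surface2d == 0:
            return None
        return 100.0 * (self.links_full3d - self.links_surface2d) / self.links_surface2d


def dimension_sensitivity_trial(
    seed: int,
    n_sites: int = 7,
    duration_days: float = 6.0,
) -> SensitivityResult:
    """One seeded replicate of the 2-D-vs-3-D network-size comparison.

    Mortality is disabled, isolating the effect of the velocity fields'
    dimensionality, and a single spawning night is simulated under the
    surface-export / sub-surface-retention shear scenario.
    """
    horizon = 24.0 + duration_days * 24.0
    bundle = shear_retention_scenario(
        n_sites=n_sites, seed=seed, duration_hours=float(np.ceil(horizon)) + 1.0
    )
    config = RunConfig(
        out_dir="unused",
        nights=[0.0],
        modes=["surface2d", "full3d"],
        duration_days=duration_days,
        mortality_rate=None,
        master_seed=seed,
    )
    out = {}
    for mode in config.modes:
        matrix, _, _, _, _ = run_night(bundle, mode, 0.0, "night-0", config)
        out[mode] = matrix
    return SensitivityResult(
        links_full3d=count_links(out["full3d"]),
        links_surface2d=count_links(out["surface2d"]),
        sinks_full3d=int((out["full3d"].col_sums > 0).sum()),
        sinks_surface2d=int((out["surface2d"].col_sums > 0).sum()),
        pct_settled_full3d=pct_settled(out["full3d"]),
        pct_settled_surface2d=pct_settled(out["surface2d"]),
    )
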