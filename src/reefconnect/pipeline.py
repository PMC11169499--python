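"""End-to-end orchestration: environment -> sites -> release -> track ->
settle -> connectivity, with deterministic per-stage seeding and a run
manifest.

A run is described by a :class:`RunConfig` (loadable from YAML).  For
every spawning night and every requested velocity mode the pipeline
produces a release schedule CSV, a trajectory NetCDF, a settlement CSV
and a connectivity matrix CSV, then summary tables (settled and
sink-site percentages, link counts), a per-mode consistency report and a
manifest recording configuration, status accounting and output
checksums.  Identical config + master seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    build_matrix,
    consistency,
    edge_list,
    export_network,
    network_to_graphml,
    scenario_table,
)
from .habitat_polygons import site_table, sites_to_geojson
from .larval_biology import (
    CompetencyWindow,
    MortalityModel,
    SiteIndex,
    build_release_schedule,
    make_mortality_hook,
    make_settlement_hook,
    settlement_records,
)
from .particle_tracker import (
    NestedVelocitySampler,
    ParticleState,
    TrackerConfig,
    accounting,
    track,
    trajectories_to_netcdf,
)
from .scenarios import SCENARIOS, ScenarioBundle
from .synthetic_environment import (
    DEPTH_AVG_2D,
    FULL_3D,
    MODES,
    SURFACE_2D,
    derive_depth_averaged,
    derive_surface,
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``nights`` are scenario-clock hours of each spawning night's midnight
    (releases then run 20:00-23:00 local that night; the clock offset to
    UTC, if any, is the caller's choice of scenario origin).
    """

    out_dir: str
    scenario: str = "westward_drift"
    scenario_params: dict = field(default_factory=dict)
    nights: list[float] = field(default_factory=lambda: [0.0, 24.0, 48.0])
    modes: list[str] = field(default_factory=lambda: [SURFACE_2D, DEPTH_AVG_2D, FULL_3D])
    duration_days: float = 30.0
    step_minutes: float = 5.0
    record_interval_minutes: float = 15.0
    min_age_days: float = 4.0
    max_age_days: float = 28.0
    mortality_rate: float | None = 0.40
    master_seed: int = 0
    write_trajectories: bool = True
    write_networks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def validate_config(config: RunConfig) -> list[str]:
    """Static invariant checks; returns a list of violations (empty = valid)."""
    problems = []
    if not config.nights:
        problems.append("nights must be non-empty")
    unknown = set(config.modes) - set(MODES)
    if unknown:
        problems.append(f"unknown modes: {sorted(unknown)}")
    if config.scenario not in SCENARIOS:
        problems.append(f"unknown scenario {config.scenario!r}")
    ratio = config.record_interval_minutes / config.step_minutes
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        problems.append("record_interval_minutes must be an integer multiple of step_minutes")
    if config.duration_days <= 0:
        problems.append("duration_days must be positive")
    if not (0 < config.min_age_days < config.max_age_days):
        problems.append("need 0 < min_age_days < max_age_days")
    if config.mortality_rate is not None and not (0 <= config.mortality_rate < 1):
        problems.append("mortality_rate must be in [0, 1) or null")
    if config.duration_days * 24.0 < config.min_age_days * 24.0:
        problems.append("duration shorter than the minimum competency age: nothing can settle")
    return problems


def stage_seed(master_seed: int, stage: str, night_id: str = "") -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2b(
        f"{master_seed}|{stage}|{night_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def mode_sampler(bundle: ScenarioBundle, mode: str) -> NestedVelocitySampler:
    """Nested fine/coarse sampler for one velocity mode of a scenario."""
    if mode == FULL_3D:
        fine, coarse = bundle.fine3d, bundle.coarse3d
    elif mode == SURFACE_2D:
        fine, coarse = derive_surface(bundle.fine3d), derive_surface(bundle.coarse3d)
    elif mode == DEPTH_AVG_2D:
        fine = derive_depth_averaged(bundle.fine3d, bundle.fine_bathymetry)
        coarse = derive_depth_averaged(bundle.coarse3d, bundle.coarse_bathymetry)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NestedVelocitySampler(
        fine=fine, coarse=coarse, bathymetry=bundle.fine_bathymetry
    )


def run_night(
    bundle: ScenarioBundle,
    mode: str,
    night_start_hours: float,
    night_id: str,
    config: RunConfig,
) -> tuple[ConnectivityMatrix, dict, pd.DataFrame, list, object]:
    """Simulate one night x mode: release, track, settle, matrix."""
    sites = bundle.sites
    schedule = build_release_schedule(
        sites,
        night_start_hours,
        seed=stage_seed(config.master_seed, "release", night_id),
        night_id=night_id,
    )
    window = CompetencyWindow(config.min_age_days, config.max_age_days)
    site_index = SiteIndex(sites)
    settle_hook = make_settlement_hook(window, site_index)
    daily_hook = None
    if config.mortality_rate is not None:
        daily_hook = make_mortality_hook(
            MortalityModel(
                daily_rate=config.mortality_rate,
                seed=stage_seed(config.master_seed, f"mortality-{mode}", night_id),
            )
        )
    particles = [
        ParticleState(
            particle_id=int(r.particle_id),
            source_site=str(r.site_id),
            x=float(r.x),
            y=float(r.y),
            z=float(r.z),
            release_time=float(r.time_h),
        )
        for r in schedule.events.itertuples()
    ]
    tracker_cfg = TrackerConfig(
        step_minutes=config.step_minutes,
        record_interval_minutes=config.record_interval_minutes,
        duration_days=config.duration_days,
        mode=mode,
        seed=stage_seed(config.master_seed, f"track-{mode}", night_id),
    )
    sampler = mode_sampler(bundle, mode)
    trajectories = track(
        particles,
        sampler,
        tracker_cfg,
        settlement_hook=settle_hook,
        daily_hook=daily_hook,
        site_ids=site_index.site_ids,
    )
    records = settlement_records(trajectories, schedule, window)
    released = schedule.events.groupby("site_id").size().to_dict()
    matrix = build_matrix(
        records, released, [s.site_id for s in sites], night_id=night_id
    )
    counts = accounting(trajectories)
    return matrix, counts, records, trajectories, schedule


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, bundle: ScenarioBundle | None = None) -> dict:
    """Run every night x mode of the configured scenario; return the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if bundle is None:
        horizon = max(config.nights) + 24.0 + config.duration_days * 24.0
        params = dict(config.scenario_params)
        params.setdefault("duration_hours", float(np.ceil(horizon)))
        params.setdefault("seed", stage_seed(config.master_seed, "environment"))
        try:
            bundle = SCENARIOS[config.scenario](**params)
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise RuntimeError(f"environment stage failed: {exc}") from exc

    bundle.fine3d.to_netcdf(out / "velocity_fine_3d.nc")
    bundle.coarse3d.to_netcdf(out / "velocity_coarse_3d.nc")
    bundle.hex_map.to_geojson(out / "hexagons.geojson")
    sites_to_geojson(bundle.sites, out / "sites.geojson")
    site_table(bundle.sites).to_csv(out / "sites.csv", index=False)

    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    night_counts: dict[str, dict] = {}
    for mode in config.modes:
        for k, night_start in enumerate(config.nights):
            night_id = f"night-{k}"
            try:
                matrix, counts, records, trajectories, schedule = run_night(
                    bundle, mode, night_start, night_id, config
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"tracking stage failed for {mode}/{night_id}: {exc}"
                ) from exc
            tag = f"{mode}_{night_id}"
            schedule.to_csv(out / f"schedule_{tag}.csv")
            records.to_csv(out / f"settlement_{tag}.csv", index=False)
            matrix.to_csv(out / f"matrix_{tag}.csv")
            if config.write_trajectories:
                trajectories_to_netcdf(trajectories, out / f"trajectories_{tag}.nc")
            if config.write_networks:
                g = export_network(
                    matrix, {s.site_id: s.centroid for s in bundle.sites}
                )
                network_to_graphml(g, out / f"network_{tag}.graphml")
                edge_list(matrix).to_csv(out / f"edges_{tag}.csv", index=False)
            matrices[(mode, night_id)] = matrix
            night_counts[tag] = counts

    summary = scenario_table(matrices)
    summary.to_csv(out / "summary.csv", index=False)
    for mode in config.modes:
        nightly = [matrices[(mode, f"night-{k}")] for k in range(len(config.nights))]
        consistency(nightly).to_csv(out / f"consistency_{mode}.csv", index=False)

    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.suffix != ".json")
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_sites": len(bundle.sites),
        "accounting": night_counts,
        "checksums": {p.name: _checksum(p) for p in outputs},
    }
    for counts in night_counts.values():
        assert counts["released"] == (
            counts["active"] + counts["settled"] + counts["dead"] + counts["exited"]
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
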