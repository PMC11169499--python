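"""Release protocol, competency, mortality and settlement of virtual larvae.

A generic broadcast-spawning coral is modelled: on each spawning night one
larva is released per site polygon every 3 minutes from 20:00 to 23:00
inclusive (61 larvae per site per night) at 2.25 m below the surface, at a
uniformly random point inside the site polygon.  Larvae are competent to
settle between 4 and 28 days after their own release and settle instantly
on the first site polygon they are recorded over while competent (the
natal site included, so self-recruitment is possible).  Mortality removes
exactly ``round(rate * n)`` of the remaining cohort at each whole-day
boundary, with the default rate of 0.40 per day.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point
import shapely

from .habitat_polygons import SitePolygon

RELEASE_DEPTH_M = 2.25
RELEASE_START_HOUR = 20.0
RELEASE_END_HOUR = 23.0
RELEASE_CADENCE_MIN = 3.0
RELEASES_PER_NIGHT = int(
    (RELEASE_END_HOUR - RELEASE_START_HOUR) * 60.0 / RELEASE_CADENCE_MIN
) + 1  # inclusive of both endpoints: 61


@dataclass(frozen=True)
class CompetencyWindow:
    """Age interval (days post-release) during which settlement is possible."""

    min_age_days: float = 4.0
    max_age_days: float = 28.0

    def __post_init__(self) -> None:
        if not (0 < self.min_age_days < self.max_age_days):
            raise ValueError("need 0 < min_age < max_age")

    def is_open(self, age_days: float | np.ndarray) -> np.ndarray:
        return (np.asarray(age_days) >= self.min_age_days) & (
            np.asarray(age_days) <= self.max_age_days
        )


@dataclass(frozen=True)
class MortalityModel:
    """Daily fractional removal of the remaining cohort."""

    daily_rate: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.daily_rate < 1.0):
            raise ValueError("daily_rate must be in [0, 1)")


@dataclass
class ReleaseSchedule:
    """Release events for one spawning night (one row per virtual larva)."""

    night_id: str
    events: pd.DataFrame  # particle_id, site_id, x, y, z, time_h
    seed: int

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False)


def build_release_schedule(
    sites: Sequence[SitePolygon],
    night_start_hours: float,
    seed: int,
    night_id: str = "night-0",
    id_offset: int = 0,
) -> ReleaseSchedule:
    """One larva per site per 3-minute slot, 20:00-23:00 inclusive.

    ``night_start_hours`` is the scenario-clock hour of the night's
    midnight (00:00); release times then run from +20.0 h to +23.0 h.
    Points are drawn uniformly inside each site polygon by rejection
    sampling from its bounding box, reproducibly from ``seed``.
    """
    rng = np.random.default_rng(seed)
    slot_times = night_start_hours + RELEASE_START_HOUR + (
        np.arange(RELEASES_PER_NIGHT) * RELEASE_CADENCE_MIN / 60.0
    )
    rows = []
    pid = id_offset
    for site in sites:
        if site.geometry.is_empty or site.geometry.area <= 0:
            raise ValueError(f"site {site.site_id} has degenerate geometry")
        xmin, ymin, xmax, ymax = site.geometry.bounds
        for t in slot_times:
            while True:
                px = rng.uniform(xmin, xmax)
                py = rng.uniform(ymin, ymax)
                if site.geometry.covers(Point(px, py)):
                    break
            rows.append((pid, site.site_id, px, py, RELEASE_DEPTH_M, float(t)))
            pid += 1
    events = pd.DataFrame(
        rows, columns=["particle_id", "site_id", "x", "y", "z", "time_h"]
    )
    return ReleaseSchedule(night_id=night_id, events=events, seed=seed)


def apply_daily_mortality(
    active_ids: Sequence[int] | np.ndarray,
    model: MortalityModel,
    day_index: int,
) -> np.ndarray:
    """Survivors after one day of mortality.

    Removes ``round(daily_rate * n)`` particles chosen uniformly without
    replacement; the draw is seeded by (model.seed, day_index) so whole
    simulations replay exactly.
    """
    if day_index < 1:
        raise ValueError("day_index counts whole days since release, >= 1")
    active = np.asarray(sorted(int(i) for i in active_ids))
    n_remove = round(model.daily_rate * active.size)
    if n_remove == 0:
        return active
    rng = np.random.default_rng([model.seed, day_index])
    doomed = rng.choice(active, size=n_remove, replace=False)
    return np.setdiff1d(active, doomed)


class SiteIndex:
    """Spatial index over site polygons for fast point-in-polygon lookup.

    Containment is boundary-inclusive.  When a point lies in several
    (touching) polygons the site earliest in the input order wins, which
    keeps settlement deterministic.
    """

    def __init__(self, sites: Sequence[SitePolygon]):
        self.sites = list(sites)
        self.site_ids = [s.site_id for s in self.sites]
        self._tree = STRtree([s.geometry for s in self.sites])

    def locate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Index of the containing site per point, -1 where none."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        out = np.full(pts.shape, -1, dtype=int)
        pt_idx, site_idx = self._tree.query(pts, predicate="covered_by")
        # earliest site in input order wins on (rare) boundary ties
        for p, s in sorted(zip(pt_idx, site_idx), key=lambda t: (t[0], t[1]), reverse=True):
            out[p] = s
        return out


def detect_settlement(
    position: tuple[float, float],
    age_days: float,
    window: CompetencyWindow,
    site_index: SiteIndex,
) -> str | None:
    """Site id the larva settles on at this record point, or None.

    Settlement requires an open competency window and the position lying
    inside (or on the boundary of) a site polygon.
    """
    if not window.is_open(age_days):
        return None
    idx = site_index.locate(np.atleast_1d(position[0]), np.atleast_1d(position[1]))[0]
    return site_index.site_ids[idx] if idx >= 0 else None


def make_settlement_hook(window: CompetencyWindow, site_index: SiteIndex):
    """Vectorized settlement callback for the particle tracker.

    Returns per-particle site indices (into ``site_index.site_ids``), -1
    for no settlement.
    """

    def hook(ids: np.ndarray, x: np.ndarray, y: np.ndarray, age_hours: float, _clock):
        if not window.is_open(age_hours / 24.0):
            return np.full(np.shape(ids), -1, dtype=int)
        return site_index.locate(x, y)

    return hook


def make_mortality_hook(model: MortalityModel):
    """Daily-boundary callback for the tracker: returns ids to remove."""

    def hook(day_index: int, active_ids: np.ndarray) -> np.ndarray:
        survivors = apply_daily_mortality(active_ids, model, day_index)
        return np.setdiff1d(np.asarray(active_ids, dtype=int), survivors)

    return hook


def settlement_records(
    trajectories,
    schedule: ReleaseSchedule,
    window: CompetencyWindow | None = None,
) -> pd.DataFrame:
    """Tabulate settled larvae: particle, source, sink, settle time, night.

    Asserts the competency contract: every settlement age lies inside the
    window and no particle settles twice (trajectories end at settlement).
    """
    window = window or CompetencyWindow()
    release_time = dict(
        zip(schedule.events["particle_id"], schedule.events["time_h"])
    )
    rows = []
    for tr in trajectories:
        if tr.status != "settled":
            continue
        t_settle = float(tr.times[-1])
        age_d = (t_settle - release_time[tr.particle_id]) / 24.0
        eps = 1e-6  # tolerate float accumulation at the exact window edge
        if not (window.min_age_days - eps <= age_d <= window.max_age_days + eps):
            raise AssertionError(
                f"particle {tr.particle_id} settled at age {age_d:.2f} d, "
                "outside the competency window"
            )
        rows.append(
            (tr.particle_id, tr.source_site, tr.settle_site, t_settle, schedule.night_id)
        )
    return pd.DataFrame(
        rows,
        columns=["particle_id", "source_site", "sink_site", "settle_time_h", "night_id"],
    )
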