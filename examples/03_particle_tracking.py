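"""Track virtual larvae through nested velocity fields with RK4.

Verifies the integrator on the analytic solid-body-rotation orbit
(fourth-order convergence) and shows a cohort drifting westward across
the nested fine/coarse domain at the study cadence (5-min steps,
15-min position records).
"""

import numpy as np

from reefconnect import ParticleState, TrackerConfig, track
from reefconnect.experiments import rk4_convergence_ratios
from reefconnect.pipeline import mode_sampler
from reefconnect.scenarios import westward_drift_scenario

errors, ratios = rk4_convergence_ratios((30.0, 15.0, 7.5, 3.75))
print("RK4 orbit-closure error (m) vs step:", ["%.2e" % e for e in errors])
print("error ratio per dt halving:", ["%.1f" % r for r in ratios],
      " (classical RK4: ~16)")

bundle = westward_drift_scenario(seed=0, duration_hours=96.0)
sampler = mode_sampler(bundle, "full3d")
particles = [
    ParticleState(i, "demo", x=float(x), y=0.0, z=2.25, release_time=0.0)
    for i, x in enumerate(np.linspace(-500, 500, 10))
]
cfg = TrackerConfig(duration_days=3.0, mode="full3d")  # 5-min dt, 15-min records
trajectories = track(particles, sampler, cfg)

tr = trajectories[0]
print(f"\n{len(trajectories)} larvae tracked for 3 days: "
      f"{tr.times.size} records each (15-min cadence)")
drift = np.mean([t.x[-1] - t.x[0] for t in trajectories])
print(f"mean net displacement {drift/1000.0:+.2f} km east "
      "(negative = westward, tide averages out, shear layer at 2.25 m depth)")
print(f"release depth maintained: z = {tr.z[-1]:.2f} m (w = 0 in this flow)")
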