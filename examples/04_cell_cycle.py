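"""Simulate one quasi-static cell cycle with slow growth.

The activation dynamics relax on a unit time scale while l creeps up a
hundred times slower, so the cell tracks the stable branch it was born on
and jumps at the NETO fold.
"""
import numpy as np
from growthzones import GrowthLaw, NondimParams, classify_growth_pattern, simulate_cycle

params = NondimParams(0.070352, 20.0, (0.5, 0.5))   # wild-type-like
traj = simulate_cycle(params, l_birth=1.05, init_state=[0.7, 0.0],
                      growth_law=GrowthLaw("linear_l", rate=1.0, rho=100))
for t, kind, zone in traj.events:
    where = f" of zone {zone + 1}" if zone is not None else ""
    l_at = float(np.interp(t, traj.t, traj.l))
    print(f"t = {t:7.2f}  l = {l_at:.4f}  {kind}{where}")
pat = classify_growth_pattern(traj)
print(f"growth pattern: {pat.label}, NETO at cycle fraction {pat.neto_cycle_fraction:.3f}")
print("The old end (zone 1) grows alone until the new end takes off when the")
print("monopolar branch ends; division follows at doubled length.")
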