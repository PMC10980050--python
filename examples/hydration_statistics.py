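"""Water residence times and contact counts around a residue.

Generates a scripted trajectory in which tagged waters make
approach-dwell-escape excursions around one residue with exponential
dwell times (mean 30 ns), then recovers the events with the dual-cutoff
clock: start when a water comes within 5 A, stop only beyond 8 A.
"""

import numpy as np

from bmcshell.hydration import residence_events
from bmcshell.synthetic import make_hydration_trajectory

traj, truth = make_hydration_trajectory(
    mean_dwell_ns=30.0, n_waters=30, n_frames=900, dt=1.0, seed=1
)
events = residence_events(traj, ("A", 1), enter_cutoff=5.0, exit_cutoff=8.0)

exact = [tuple(e) for e in events] == [tuple(e) for e in truth]
durations_ns = np.array([e.duration_frames for e in events]) * traj.dt
print(f"scripted events: {len(truth)}, recovered: {len(events)}, "
      f"exact agreement: {exact}")
print(f"mean residence time: {durations_ns.mean():.1f} ns "
      f"(generator truth: 30 ns)")
print(f"longest single visit: {durations_ns.max():.0f} ns")
print("The 3 A hysteresis band (5 A entry, 8 A exit) prevents boundary")
print("flicker from fragmenting one visit into many short events; a")
print("mean near 30 ns shows the clock neither merges nor splits them.")
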