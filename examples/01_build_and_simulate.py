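"""Build the toy host-guest complex and simulate the three binding scenarios.

The guest's mass center follows a mean-reverting walk along the host axis;
positive coordinates are the wide (secondary-hydroxyl) rim side.  The final
line classifies each trajectory from its last-20-ns window mean.
"""

from cycloplex import (
    ScenarioSpec,
    build_toy_complex,
    classify_binding_mode,
    signed_ring_distance,
)
from cycloplex.synthetic import simulate_replicates

system, xyz = build_toy_complex()
print(f"toy complex: {system.n_atoms} atoms, {system.n_units} host units")

for scenario, mean in [("stable_wide", 3.0), ("stable_narrow", -3.0),
                       ("dissociating", 0.0)]:
    spec = ScenarioSpec(scenario=scenario, ou_mean=mean, n_frames=900,
                        timestep_label=0.1, seed=1)
    for traj in simulate_replicates(system, xyz, spec, n_replicates=3):
        trace = signed_ring_distance(system, traj, "guest")
        window = traj.last_window(20.0)
        mode = classify_binding_mode(trace, window)
        print(f"{scenario:14s} {traj.replicate_id}: window mean "
              f"{trace.values[window].mean():+6.2f} A -> {mode}")
# A positive window mean inside (1.98, 3.95] A means the guest sits at the
# wide rim; |mean| > 8 A means the complex fell apart.
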