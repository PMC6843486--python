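# Demo run configuration for `cycloplex run-all`.
# Every stage's knobs in one place; seeds are explicit so reruns are
# byte-identical.
seed: 7
n_frames: 900            # frames per replicate
timestep_ns: 0.05        # ns per frame -> 45 ns runs
window_ns: 20.0          # trailing analysis window
contact_cutoff: 3.0      # A
hbond_cutoff: 3.5        # A
rim_half_height: 3.95    # A
pes_temperature: 303.0   # K
gbsa_systems: [stable_wide]
gbsa_tds: {stable_wide: -17.7}   # kcal/mol, entropy input per system
gbsa_n_snapshots: 100
sasa_stride: 4
sasa_points: 240
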