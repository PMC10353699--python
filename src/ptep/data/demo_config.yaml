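# Demo pipeline configuration: small synthetic accumulation recording,
# tracked, analyzed and characterized end-to-end.
out_dir: ptep_demo_out
seed: 7
simulate:
  scenario: accumulation
  n_particles: 60
  duration_s: 12.0
  frame_rate: 10.0
track:
  radius_range: [2, 4]
  sensitivity: 0.35
  min_length_fraction: 0.25
kinematics:
  particle:
    diameter_um: 2.0
    density: 1050.0
accumulation:
  laser_on_s: 0.0
  fit_duration_s: 10.0
  smooth_window_frames: 60
physics:
  fluid_density: 997.0
  fluid_viscosity: 1.0e-3
  characteristic_length_um: 220.0
  gravity: 9.81
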