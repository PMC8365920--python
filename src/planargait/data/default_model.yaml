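# Default planar walker model: ~75 kg, ~1.8 m anthropometry from standard
# segment-parameter tables. Seven segments (HAT trunk, 2x thigh/shank/foot),
# sagittal plane. Units: kg, m, kg m^2, N, rad, SI throughout.
schema: planargait-model-v1
gravity: 9.81

segments:
  # com_offset measured from the proximal joint along the segment.
  trunk: {mass: 50.85, length: 0.80, com_offset: 0.35, inertia: 3.00}
  thigh: {mass: 7.50,  length: 0.44, com_offset: 0.19, inertia: 0.120}
  shank: {mass: 3.50,  length: 0.43, com_offset: 0.19, inertia: 0.050}
  foot:  {mass: 1.10,  length: 0.25, com_offset: 0.10, inertia: 0.010}

joints:
  # limits [min, max] in rad; hip flexion +, knee flexion -, ankle dorsiflex +
  hip:   {limits: [-0.70, 2.10]}
  knee:  {limits: [-2.60, 0.02]}
  ankle: {limits: [-0.90, 0.70]}
joint_limit_stiffness: 2000.0  # N m / rad outside the limit
joint_limit_damping: 30.0      # N m s / rad, only while violating
joint_damping: 0.3             # N m s / rad passive viscous damping

contact:
  stiffness: 1.2e6      # N / m^exponent (Hunt-Crossley style)
  exponent: 1.5
  damping: 1.2          # s/m velocity coefficient in the normal law
  friction_mu: 0.8
  friction_vel: 0.05    # m/s smoothing scale of the Coulomb law
  spheres:              # foot frame: x forward from the ankle, y up
    - {x: -0.05, y: -0.05, r: 0.025}
    - {x:  0.08, y: -0.05, r: 0.025}
    - {x:  0.20, y: -0.05, r: 0.025}

# Per-leg muscle template (mirrored to _R / _L). Moment arms (m) follow the
# sign convention: hip flexion +, knee flexion -, ankle dorsiflexion +; a
# positive arm at a joint means the muscle shortens as that angle increases.
# Neutral MTU length is l_opt + l_slack, i.e. l_ce_norm = 1 in quiet standing.
muscles:
  HAB:  {f_max: 3000, l_opt: 0.09, l_slack: 0.07, v_max: 12, moment_arms: {}}
  HAD:  {f_max: 4500, l_opt: 0.10, l_slack: 0.13, v_max: 12, moment_arms: {}}
  HFL:  {f_max: 2000, l_opt: 0.11, l_slack: 0.10, v_max: 12,
         moment_arms: {hip: 0.08}}
  GLU:  {f_max: 1500, l_opt: 0.11, l_slack: 0.13, v_max: 12,
         moment_arms: {hip: -0.08}}
  HAM:  {f_max: 3000, l_opt: 0.10, l_slack: 0.31, v_max: 12,
         moment_arms: {hip: -0.08, knee: -0.05}}
  RF:   {f_max: 1200, l_opt: 0.08, l_slack: 0.35, v_max: 12,
         moment_arms: {hip: 0.08, knee: 0.06}}
  VAS:  {f_max: 6000, l_opt: 0.08, l_slack: 0.23, v_max: 12,
         moment_arms: {knee: 0.06}}
  BFSH: {f_max: 350,  l_opt: 0.12, l_slack: 0.10, v_max: 12,
         moment_arms: {knee: -0.04}}
  GAS:  {f_max: 1500, l_opt: 0.05, l_slack: 0.40, v_max: 12,
         moment_arms: {knee: -0.05, ankle: -0.05}}
  SOL:  {f_max: 4000, l_opt: 0.04, l_slack: 0.26, v_max: 12,
         moment_arms: {ankle: -0.06}}
  TA:   {f_max: 800,  l_opt: 0.06, l_slack: 0.24, v_max: 12,
         moment_arms: {ankle: 0.04}}
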