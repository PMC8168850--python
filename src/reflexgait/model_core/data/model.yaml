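# Planar 9-DoF walking model, version 1.
#
# The skeleton is height 1.80 m / mass 75.16 kg with the head, arms and trunk
# (HAT) lumped rigidly with the pelvis.  Segment masses, lengths, COM offsets
# and inertias follow the public Delp-lineage planar gait models (gait2392 /
# gait10dof18musc grouping), scaled to the stated totals; segment masses are
# renormalized at load time so their sum equals total_mass exactly.
#
# Frames: x forward, y up.  Each segment frame originates at its proximal
# joint (pelvis frame at the hip joint centre, femur at the hip, shank at the
# knee, foot at the ankle).  Angle conventions: positive hip flexion, positive
# knee flexion, positive ankle dorsiflexion, positive trunk forward lean.
version: 1
total_height: 1.8
total_mass: 75.16
gravity: 9.81

segments:
  hat:    {mass: 46.0138, length: 0.62, com: [0.0, 0.32], inertia: 3.20}
  femur:  {mass: 9.3014,  length: 0.41, com: [0.0, -0.17], inertia: 0.134}
  shank:  {mass: 3.7075,  length: 0.43, com: [0.0, -0.19], inertia: 0.051}
  foot:   {mass: 1.5666,  length: 0.26, com: [0.05, -0.05], inertia: 0.010}

# Head reference point (HAT frame): used for the head-acceleration penalty.
head_point: [0.0, 0.62]

joint_limits:
  # Soft passive stops (rad); restoring stiffness (N*m/rad) and damping
  # (N*m*s/rad) act only beyond the stop.  These are physical articular
  # limits, wider than the desired gait ranges used by the objective.
  hip:   {range: [-0.90, 1.80]}
  knee:  {range: [-0.02, 2.40]}
  ankle: {range: [-1.00, 0.70]}
  stop_stiffness: 1000.0
  stop_damping: 10.0
  # Light viscous joint friction applied everywhere (N*m*s/rad).
  damping: 0.1

contact:
  # Hunt-Crossley normal force  F = k * d^1.5 * (1 + c * ddot)  clamped >= 0,
  # with piecewise-linear regularized Coulomb friction |Ft| <= mu * Fn.
  stiffness: 2.5e6        # N / m^1.5
  dissipation: 1.0        # s / m
  friction: 0.9
  regularization_velocity: 0.05   # m/s
  spheres:
    # foot-frame centre [x, y] and radius; one calcaneus + two toe spheres.
    - {name: calcn, pos: [-0.045, -0.045], radius: 0.050}
    - {name: toe1,  pos: [0.115, -0.070], radius: 0.025}
    - {name: toe2,  pos: [0.160, -0.070], radius: 0.025}

muscles:
  # Hill-type rigid-tendon units.  f_max (N), l_opt (m), v_max (l_opt/s),
  # fast_twitch: fraction of fast-twitch fibres (metabolic model).
  # ref_norm_fiber_length: normalized fiber length in the upright reference
  # pose (all joint angles zero); the tendon slack length is derived from it
  # at load time so path geometry and fiber operating range stay consistent.
  # path: via-points as [segment, x, y]; segment is pelvis|femur|shank|foot.
  GMAX:
    f_max: 1944.0
    l_opt: 0.157
    v_max: 10.0
    fast_twitch: 0.45
    ref_norm_fiber_length: 1.00
    base_length: 0.27
    arms: {hip: -0.062}
  ILPSO:
    f_max: 2342.0
    l_opt: 0.132
    v_max: 10.0
    fast_twitch: 0.45
    ref_norm_fiber_length: 1.00
    base_length: 0.22
    arms: {hip: 0.045}
  HAMS:
    f_max: 2700.0
    l_opt: 0.110
    v_max: 10.0
    fast_twitch: 0.40
    ref_norm_fiber_length: 0.95
    base_length: 0.45
    arms: {hip: -0.060, knee: 0.026}
  RF:
    # patellar wrap: constant moment arms (via-point polylines lose the
    # extensor lever at deep knee flexion without a patella)
    f_max: 1169.0
    l_opt: 0.114
    v_max: 10.0
    fast_twitch: 0.55
    ref_norm_fiber_length: 0.95
    base_length: 0.45
    arms: {hip: 0.036, knee: -0.042}
  VAS:
    f_max: 4530.0
    l_opt: 0.089
    v_max: 10.0
    fast_twitch: 0.50
    ref_norm_fiber_length: 0.95
    base_length: 0.28
    arms: {knee: -0.042}
  BFSH:
    f_max: 804.0
    l_opt: 0.173
    v_max: 10.0
    fast_twitch: 0.50
    ref_norm_fiber_length: 1.00
    base_length: 0.26
    arms: {knee: 0.028}
  GAS:
    f_max: 2241.0
    l_opt: 0.064
    v_max: 10.0
    fast_twitch: 0.45
    ref_norm_fiber_length: 0.95
    base_length: 0.48
    arms: {knee: 0.020, ankle: -0.048}
  SOL:
    f_max: 3549.0
    l_opt: 0.050
    v_max: 10.0
    fast_twitch: 0.20
    ref_norm_fiber_length: 0.90
    base_length: 0.32
    arms: {ankle: -0.048}
  TA:
    f_max: 905.0
    l_opt: 0.098
    v_max: 10.0
    fast_twitch: 0.30
    ref_norm_fiber_length: 0.95
    base_length: 0.27
    arms: {ankle: 0.040}

# Hill-curve constants (documented here, consumed by model_core.muscles):
hill:
  fl_width: 0.45          # Gaussian active force-length: exp(-((l-1)/w)^2)
  fv_shortening_a: 0.25   # hyperbolic Hill constant a/f0
  fv_lengthening_max: 1.4 # eccentric force plateau
  fv_lengthening_slope: 7.5
  passive_strain: 0.6     # strain at which passive force reaches f_max
  passive_exponent: 4.0
  damping: 0.01           # parallel damping, f_max per (l_opt/s)
  fiber_length_clamp: [0.4, 1.6]

# Default initial condition: upright stance with a small forward push and a
# slightly split stance (left leg leading); configurable per simulation.
initial_state:
  pelvis_velocity: [1.0, 0.0]
  ground_penetration: 0.003     # m, initial contact depth (static support)
  # mid-gait start: right leg in stance under the body, left leg mid-swing
  pose:
    pelvis_tilt: 0.03
    hip_l: 0.40
    knee_l: 0.30
    ankle_l: 0.05
    hip_r: 0.00
    knee_r: 0.05
    ankle_r: 0.00
  # initial activations: weight-bearing extensors pre-activated so the
  # force-feedback loops have a working point to latch onto
  activation:
    default: 0.05
    VAS: 0.30
    SOL: 0.25
    GMAX: 0.20
    HAMS: 0.15
    GAS: 0.10
    TA: 0.10
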