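# Methods

`reflexgait` simulates planar human walking driven entirely by spinal
reflex circuits, optimizes the reflex parameters against gait targets
with CMA-ES, and analyzes the resulting solution datasets to identify
the reflex parameters that modulate walking speed, step length and step
duration. This note documents the models, the numerical choices, and
what the scaled-down test evidence does and does not show.

## Musculoskeletal model

The skeleton is a 9-DoF planar kinematic tree: a 3-DoF planar joint
between the pelvis and the ground plus hip, knee and ankle revolutes per
leg. The head, arms and trunk are lumped rigidly with the pelvis into a
single HAT segment; the trunk forward-lean angle θ used by the balance
controller is the pelvis tilt coordinate. Totals are height 1.80 m and
mass 75.16 kg; segment masses, lengths, COM offsets and inertias follow
the public Delp-lineage planar gait models, with masses renormalized at
load time so the segment sum equals the stated total exactly
(`model_core/data/model.yaml`, versioned). Angle conventions are
positive hip flexion, knee flexion, ankle dorsiflexion and forward
trunk lean.

Equations of motion are assembled in world coordinates (COM-Jacobian
mass matrix, Newton–Euler bias pass with the gravity base-acceleration
trick) and integrated by fixed-step semi-implicit Euler at 1e-4 s, the
controller sampled every step. This integrator is reproducible, makes
delay buffers trivially indexable, and in the passive contact-free model
drifts mechanical energy by <0.1 % per simulated second (tested). Soft
joint stops (1000 N·m/rad beyond the articular range, 10 N·m·s/rad
damping) and a light 0.1 N·m·s/rad viscous joint friction bound the
behavior in falls.

### Muscle–tendon units

Nine Hill-type rigid-tendon units per leg (GMAX, HAMS, ILPSO, RF, VAS,
BFSH, GAS, SOL, TA). Curves: Gaussian active force–length
(width 0.45), Hill hyperbola for shortening (a/f0 = 0.25) with a
saturating eccentric branch (plateau 1.4), exponential passive curve
(reaches f_max at 60 % strain), small parallel damping (0.01 f_max per
v_max), fiber lengths clamped to [0.4, 1.6] l_opt before curve
evaluation. The tendon slack length of every muscle is *derived* at
load time from a configured reference normalized fiber length in the
upright pose, so path geometry and fiber operating range stay mutually
consistent whatever the path constants.

Muscle paths support two forms. Via-point polylines give exact
lengths and analytic moment arms (r_j = −∂L/∂q_j, verified against
finite differences and a brute-force path walker in the tests). The
*shipped* walking model, however, uses constant (cam-like) moment arms
for every muscle: a straight polyline without wrapping surfaces loses
or even flips its lever at deep joint angles — the quadriceps line
crosses to the flexion side of the knee past ~60° (there is no
patella), and the Achilles line passes through the ankle centre in deep
dorsiflexion — turning stretch reflexes into runaway positive-feedback
loops. Constant arms are the degree-0 case of the polynomial-arm
approximation and are the standard choice in reflex-walking models.
Arm magnitudes (m): GMAX hip −0.062, HAMS hip −0.060/knee +0.026,
ILPSO hip +0.045, RF hip +0.036/knee −0.042, VAS knee −0.042, BFSH
knee +0.028, GAS knee +0.020/ankle −0.048, SOL ankle −0.048, TA ankle
+0.040.

### Contact

Three spheres per foot (calcaneus r = 5 cm, two toe spheres r = 2.5 cm)
with Hunt–Crossley normal force F = k δ^1.5 (1 + c δ̇), k = 2.5e6
N/m^1.5, c = 1.0 s/m, clamped non-negative, and piecewise-linear
regularized Coulomb friction (μ = 0.9, regularization velocity
0.05 m/s), evaluated at the material point at the bottom of each sphere
so rolling contact is handled correctly.

## Reflex controller

Five gait sub-phases per leg — early stance (ES), mid-stance (MS),
pre-swing (PS), swing (S), landing preparation (LP) — cycled strictly in
that order. Triggers (thresholds are optimizable controller
parameters): ES→MS when the pelvis passes the stance ankle by a
distance threshold; MS→PS on a *fresh* contralateral landing (the other
leg loaded above the body-weight-fraction threshold and in its ES);
PS→S at own unloading (toe-off); S→LP when the swing ankle passes the
pelvis by a distance threshold (which may be negative, i.e. landing
preparation can begin while the foot is still behind the pelvis) or
immediately on an early ground contact; LP→ES at own loading (heel
strike).

Stimulation pathways per muscle and phase (wiring in
`reflex_controller/data/wiring.yaml`, fully editable):

- feedforward u_C = k_C;
- stretch u_L = k_L · max(0, l̃(t−t_D) − l_0);
- velocity u_V = k_V · max(0, ṽ(t−t_D));
- force (Golgi) u_F = k_F · f̃(t−t_D), including inhibitory
  cross-projections (TA is inhibited by SOL force; VAS by BFSH stretch;
  ILPSO by HAMS stretch in swing);
- PD trunk balance u_PD = k_p(θ(t−t_D) − θ_0) + k_v θ̇(t−t_D), applied
  to the hip muscles during stance phases with its positive part routed
  to the extensors (GMAX, HAMS) and its negative part to the flexor
  (ILPSO).

Signals are normalized by l_opt and f_max. Neural delays are 5 ms for
hip, 10 ms for knee and 20 ms for ankle muscles, realized as ring
buffers at the 1e-4 s controller rate with nearest-sample reads
(≤0.05 ms quantization, far below every delay). Total stimulation is
clamped to [0.01, 1]; the floor avoids exactly-zero excitation.
Activation follows da/dt = (u − a)/τ with τ = 10 ms, discretized
exactly (a′ = u + (a−u)e^(−dt/τ)), which is unconditionally stable and
testable in closed form.

The wiring follows the phase-gated reflex scheme of the
reflex-walking literature qualitatively: plantarflexor positive force feedback in stance (the
key MS–PS gains), hamstrings and TA stretch reflexes with
phase-specific gains/offsets, iliopsoas stretch drive in pre-swing and
swing, GMAX/HAMS/TA stretch in landing preparation. Two additions were
needed for a stable planar gait and are plain config entries: a
rectus-femoris stretch reflex in S–LP (quadriceps stretch fires on knee
flexion, controlling the swing knee whip while aiding hip flexion) and
a small VAS stance feedforward constant.

## Metabolics

Umberger-style energetics per muscle (W/kg muscle): activation +
maintenance heat (25 + 128·f_FT) · S with S = 1.5 and the maintenance
portion scaled by the force–length curve above optimal length;
shortening/lengthening heat with slow/fast partitioning (α_ST = 100 /
v̂max_ST, v̂max_ST = 0.4 v_max; α_FT = 153 / v_max; lengthening
coefficient 4 α_ST) and activation scaling (A^2 concentric, A^0.6
otherwise); positive fiber work rate only, with eccentric (negative)
work discarded — the Uchida treatment — and the total rate clamped
non-negative. A = a (the stimulation/activation distinction of the
original model is collapsed; both are recorded, and the simplification
is documented here). Muscle mass is density × PCSA × l_opt with
density 1059.7 kg/m³ and specific tension 2.5e5 N/m²; fiber-type
fractions are per-muscle model parameters (SOL 0.2 … RF 0.55).

Effort is energy per distance per body mass, J/(kg·m): the basal rate
1.2 W/kg body mass and every muscle's (heat + work) rate × muscle mass
are time-integrated over the simulation before normalizing by distance
× body mass (the rates must be integrated for the units to come out;
effort is invariant to trace resampling to <0.1 %, tested).

## Objective

Seven penalty components summed: stability w(time_max −
time_sim)/time_max with time_max = 15 s and early termination when COM
height falls below 0.8 of its initial value (strict inequality);
absolute-difference penalties for speed, step length and step duration
against scalar targets or bands; weighted effort; desired-joint-range
penalty (hip [−16.2, 42.0]°, knee [−1.3, 68.2]°, ankle [−27.7, 15.5]°)
as the per-joint time-averaged exceedance in degrees (worse side),
summed over joints — scale-free in simulation duration and on the scale
of the per-joint selection ceilings (0.5, 0.5, 3); and the
same time-averaged-exceedance construction for head acceleration
outside [−2.45, 2.45] m/s² forward and [−4.9, 4.9] m/s² vertical.
Weights per protocol set: (stability, speed, sl, sd, effort, joints,
head) = (100, 100, 0, 0, 1, 0.1, 0.25) for the speed set, with sl or sd
weight 1 and effort weight 0.1 for the step-length and step-duration
sets.

Step events are heel strikes: the calcaneus-sphere vertical force
rising through 20 N, with a 0.2 s per-foot refractory interval against
contact chatter. Metrics are averaged from the second heel strike
onward (the launch transient is discarded); step length is the fore-aft
distance between consecutive contralateral calcaneus contact points, so
speed ≈ sl/sd holds by construction on steady gaits. Speed is the
step-windowed pelvis average when at least three events exist, else the
whole-trace average forward progression (the recorded average speed is
still defined for falling gaits, which also gives the optimizer a
gradient). Sets 2/3 fix the complementary characteristic to the band
[0.68, 0.72] (s or m) and set the implied speed target from the band
centre (sl/0.70 and 0.70/sd).

## Optimization

A self-contained (μ/μ_w, λ)-CMA-ES (rank-one + rank-μ covariance
updates, cumulative step-size adaptation) drives the full parameter
vector: reflex gains/offsets, feedforward constants, PD balance
constants and state thresholds (41 parameters). Per-parameter sampling
scales seed the initial covariance (C₀ = diag(std²)) with σ = 1
dimensionless — equivalent to the unit-scaled search space while
keeping encode/decode bit-exact. Bounds (gains [0, 10], offsets
[0.4, 1.4], constants [0, 0.5], θ₀ [−0.3, 0.3] rad, thresholds in
their units) are enforced by clipping with a quadratic out-of-bounds
penalty. Every evaluated candidate whose simulation completes is
logged as a solution record, so one run yields a dataset of gaits, and
identical seeds yield bit-identical candidate sequences.

The full campaign protocol (three sets, 12/9/9 runs, 1500 generations
at λ = 16, 15 s simulations) is far beyond a desktop budget; the package
runs the same machinery at reduced sizes. The bundled reference
solution (`data/reference_solution.yaml`) is the best mid-range
(1.0 m/s) speed-protocol gait from the package's own runs (~500
generations total, staged 8 s → 15 s horizons); it walks the full 15 s
with cycle-converged joint angles at speed 1.00 m/s, step length
0.76 m, step duration 0.75 s. It seeds the step-length/step-duration
sets and all scaled validation runs. Default scaled sizes used by the
tests and the acceptance script: refinement 6 generations × λ 8 × 10 s
simulations; key-only vs nonkey-only frozen comparisons 10 generations
× λ 8 × 8 s simulations at 0.6 and 1.6 m/s targets, with the achieved
range taken as the union of non-falling solution speeds.

Initial condition: a mid-gait start —
one leg in stance under the body, the other mid-swing, pelvis moving
forward at 1.0 m/s, weight-bearing extensors pre-activated and ~3 mm of
initial contact penetration carrying static load. A standing start
turns every optimization into a gait-initiation problem first.

## Dataset analysis

Selection keeps solutions that (i) complete the simulation without a
fall and converge to a constant joint-angle oscillation (RMS difference
between the last two cycle-normalized gait cycles < 2°, at least three
full cycles), (ii) have effort below 4 J/(kg·m) for speeds in
[0.8, 1.3] m/s and below 8 otherwise, (iii) have per-joint penalties
below 0.5 (hip, knee) and 3 (ankle), and (iv) for sets 2/3, keep the
fixed characteristic within 0.69 ± 0.01 s / 0.72 ± 0.02 m. Rejections
carry the first failed rule; selection is idempotent and
order-independent.

Key-parameter identification: Pearson correlation of each *reflex*
parameter (feedforward, balance and state parameters are excluded)
with speed on the set-1 records, step length on set 2 and step
duration on set 3; a parameter is key when |c| > 0.6 on any
characteristic, and the other half of a (k_L, l_0) stretch pair is
added whenever one half is selected. Per-set regressions then take the
lowest polynomial order (1–3) with R² > 0.7, else order 3 with a
below-threshold flag. Range comparison reports per-characteristic
[min, max] and width coverage relative to the full dataset.

## Synthetic data

`synth_solutions` builds per-set solution tables with *planted*
correlations: the characteristic is drawn uniformly over the published
ranges, the metrics are kinematically consistent (speed = sl/sd), and a
planted parameter is c·b̃ + √(1−c²)·ẽ in standardized units, where b̃
is the (standardized) linear/quadratic/cubic base and ẽ is noise
orthogonalized in-sample against both the base and the characteristic —
so the realized sample Pearson correlation equals the planted c
*exactly*, and recovery failures can only come from the analysis, not
from sampling luck. With `exact=False` the closed-form sampling error
of a correlation applies instead. The default table plants the
default nine-parameter key pattern (three stance-phase step-length
modulators, four three-way modulators, two compensating landing-phase
modulators) with the published correlation magnitudes.

`synth_trace` builds kinematically consistent walking traces (heel
strikes alternating feet at the step duration, contact abscissae spaced
by the step length, constant-height COM with an optional exact-time
fall, sinusoidal joint waveforms, constant head accelerations). The
traces are kinematically, not dynamically, consistent: passing metric
and penalty tests on them validates the measurement and analysis code,
not the physics.

## Known limitations

- The effort of the bundled gait (~8.7 J/(kg·m) at 1.0 m/s) exceeds the
  4 J/(kg·m) selection ceiling: with only ~500 generations of
  optimization, co-contraction has not been minimized away, so the
  published effort filter would reject the package's own scaled-run
  gaits. The filter is implemented verbatim and exercised on synthetic
  records.
- The knee joint-range penalty of the bundled gait (0.83°) is above the
  0.5 selection ceiling for the same reason.
- The walker is robust to the default start but not to arbitrary
  initial speeds (e.g. a 0.9 m/s push can destabilize it); basins of
  attraction were not optimized.
- Numerical equivalence with prior reflex-walking implementations is
  not claimable: segment and muscle constants are adapted from the
  public planar gait-model lineage rather than copied from any single
  reference model.
- The key-vs-nonkey frozen-run ordering is a full-scale emergent result;
  at the scaled sizes above it holds for the shipped test conditions but
  remains noisy across optimizer seeds.
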