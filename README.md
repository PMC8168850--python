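# reflexgait

Reflex-driven planar walking: forward simulation, gait optimization and
key-reflex analysis.

Human locomotion can be modulated — faster or slower, longer or shorter
steps — without any change to feedforward rhythm generators, purely by
re-tuning spinal reflexes. `reflexgait` is a research package for
studying that hypothesis in simulation. It contains, end to end:

- a **planar neuromusculoskeletal model**: 9 DoF (3-DoF planar
  pelvis–ground joint, hip/knee/ankle per leg), 9 Hill-type
  muscle–tendon units per leg (GMAX, HAMS, ILPSO, RF, VAS, BFSH, GAS,
  SOL, TA), Hunt–Crossley foot–ground contact on three spheres per
  foot, scaled to height 1.8 m / mass 75.16 kg;
- a **phase-gated reflex controller**: five gait sub-phases per leg
  (ES, MS, PS, S, LP) switched by a load/geometry state machine; muscle
  stimulation composed from feedforward constants k_C, stretch
  feedback k_L·max(0, l̃(t−t_D) − l_0), velocity feedback
  k_V·max(0, ṽ(t−t_D)), Golgi force feedback k_F·f̃(t−t_D) (including
  inhibitory projections such as SOL→TA) and a PD trunk-balance term
  k_p(θ−θ_0) + k_v θ̇ on the hip muscles; neural delays of 5/10/20 ms
  (hip/knee/ankle) and first-order activation dynamics
  da/dt = (u−a)/τ, τ = 10 ms;
- an **Umberger-style metabolic model** (with the eccentric-work
  discard) yielding walking effort in J/(kg·m);
- a **seven-component gait objective** (stability, speed, step length,
  step duration, effort, joint ranges, head acceleration) and **CMA-ES
  optimization** of the 41 controller parameters under three protocol
  sets: target speeds; target step lengths at fixed step duration
  [0.68, 0.72] s; target step durations at fixed step length
  [0.68, 0.72] m;
- the **solution-dataset analysis**: selection filters (stability and
  cycle convergence, effort ceilings 4/8 J/(kg·m), per-joint penalty
  ceilings 0.5/0.5/3), Pearson screening of each reflex parameter
  against speed / step length / step duration at threshold |c| > 0.6
  with stretch-pair (k_L ↔ l_0) augmentation, bounded-order polynomial
  regression (lowest order with R² > 0.7, max 3), and key-only vs
  nonkey-only frozen-optimization range comparisons;
- **synthetic-data generators** that plant known correlation structure
  in solution tables (realized exactly in-sample) and build
  kinematically consistent gait traces with known step events, so the
  whole analysis chain is testable without running optimizations.

A tuned reference solution ships with the package: a mid-range gait
that walks the full 15 s simulation at 1.0 m/s.

## Worked example

```python
import numpy as np
from reflexgait import GaitSimulator
from reflexgait.reference import reference_solution
from reflexgait.gait_objective import measure, ObjectiveConfig
from reflexgait.metabolics import MuscleEnergetics

sim = GaitSimulator()
values = reference_solution(sim.params)
trace = sim.run(values, duration=15.0)
metrics = measure(trace, ObjectiveConfig(),
                  MuscleEnergetics.from_model(sim.model))
print(f"fell: {metrics.fall}   steps: {len(metrics.events)}")
print(f"speed: {metrics.speed:.3f} m/s   "
      f"step length: {metrics.step_length:.3f} m   "
      f"step duration: {metrics.step_duration:.3f} s")
print(f"effort: {metrics.effort:.2f} J/(kg*m)")
```

prints

```
fell: False   steps: 20
speed: 1.000 m/s   step length: 0.759 m   step duration: 0.754 s
effort: 8.67 J/(kg*m)
```

— the bundled reflex parameter set walks all 15 simulated seconds
(20 heel strikes), averages exactly the 1.0 m/s target with step
length/duration obeying speed ≈ sl/sd, and spends 8.7 J per kg body
mass per metre (higher than an energy-optimal human gait; see
`docs/methods.md` on optimization budget). `trace` is a 1 kHz
column-oriented record (joint kinematics, per-muscle
activation/stimulation/force/fiber state, ground reaction forces, COM
and head kinematics, phase labels) that round-trips through CSV.

To optimize from scratch or run an analysis, see
`reflexgait.optimization` (`OptimizationProtocol`, `run_optimization`,
`run_set`, `freeze_and_optimize`) and `reflexgait.solution_analysis`
(`select`, `correlations`, `identify_key`, `fit_regression`,
`build_report`, `compare_ranges`).

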