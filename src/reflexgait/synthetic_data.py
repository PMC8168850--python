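"""Synthetic solution tables and kinematic traces for analysis testing.

Two generators make every analysis stage testable without running gait
optimizations:

* :func:`synth_solutions` builds per-set solution records whose reflex
  parameters carry *planted* correlations with the set's gait
  characteristic.  With ``exact=True`` (default) the noise component is
  orthogonalized against the characteristic, so the realized sample
  Pearson correlation equals the planted value exactly; with
  ``exact=False`` it holds in expectation with the closed-form sampling
  error of a correlation coefficient.

* :func:`synth_trace` builds a kinematically consistent walking trace
  (heel-strike events, contact positions, COM height, joint waveforms,
  head accelerations) with every ground-truth quantity known, including
  an optional fall at a requested time.

Traces are only kinematically, not dynamically, consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_objective import GaitMetrics
from .reflex_controller.params import ReflexParameterSet, load_wiring
from .solution_analysis import SolutionRecord
from .trace import CH_INDEX, NCH, SimulationTrace

DEG2RAD = np.pi / 180.0


# ---------------------------------------------------------------------
# planted solution tables
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    param: str
    set_id: int                  # 1 speed, 2 step length, 3 step duration
    correlation: float           # target Pearson c (sign included)
    form: str = "linear"         # linear | quadratic | cubic


@dataclass
class PlantedEffectSpec:
    """Specification of one synthetic solution table."""
    n: int = 150                 # records per set
    seed: int = 0
    exact: bool = True
    effects: list = field(default_factory=list)
    param_spread: float = 0.12   # parameter SD as a fraction of bound width
    char_ranges: dict = field(default_factory=lambda: {
        1: (0.45, 1.71),         # speed, m/s
        2: (0.45, 0.88),         # step length, m
        3: (0.51, 0.91),         # step duration, s
    })

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("need n >= 10 records per set")
        for e in self.effects:
            if not -1.0 <= e.correlation <= 1.0:
                raise ValueError(f"{e.param}: |c| must be <= 1")
            if e.set_id not in (1, 2, 3):
                raise ValueError(f"{e.param}: bad set id")
            if e.form not in ("linear", "quadratic", "cubic"):
                raise ValueError(f"{e.param}: bad form")

    @classmethod
    def default(cls, n: int = 150, seed: int = 0) -> "PlantedEffectSpec":
        """Nine-key-parameter pattern: three stance-phase step-length
        modulators, four three-way modulators and two compensating
        landing-phase modulators."""
        t3 = {
            "L0HAMS_ES-MS": (0.4892, 0.7827, 0.1312),
            "KFSOL_MS-PS": (0.9082, 0.8156, 0.3632),
            "KFGAS_MS-PS": (0.8978, 0.7074, 0.1348),
            "KLILPSO_PS": (-0.6931, -0.8029, 0.6363),
            "L0ILPSO_S": (-0.4689, -0.2328, 0.7409),
            "KLGMAX_LP": (0.7285, 0.4041, -0.6454),
            "L0TA_LP": (-0.8121, -0.5978, 0.3431),
            "KLHAMS_LP": (0.1452, -0.4781, -0.6072),
            "L0HAMS_LP": (0.3382, 0.8707, 0.7602),
        }
        effects = [PlantedEffect(p, s + 1, c)
                   for p, cs in t3.items() for s, c in enumerate(cs)]
        return cls(n=n, seed=seed, effects=effects)

    def planted_key(self, params: ReflexParameterSet,
                    threshold: float = 0.6) -> list[str]:
        """The key set this spec plants (threshold + stretch partners)."""
        key = sorted({e.param for e in self.effects
                      if abs(e.correlation) > threshold})
        out = list(key)
        for n in key:
            p = params.stretch_partner(n)
            if p is not None and p not in out:
                out.append(p)
        return sorted(out)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _orthonormal_noise(rng, y_std: np.ndarray, base_std: np.ndarray
                       ) -> np.ndarray:
    """Unit-variance noise orthogonal (in sample) to y and the base."""
    e = rng.standard_normal(y_std.size)
    for v in (y_std, base_std):
        e = e - (e @ v) / (v @ v) * v
    return _standardize(e)


def synth_solutions(spec: PlantedEffectSpec,
                    params: ReflexParameterSet | None = None) -> dict:
    """Generate records_by_set ({1: [...], 2: [...], 3: [...]})."""
    if params is None:
        params, _, _ = load_wiring()
    for e in spec.effects:
        if e.param not in params.index:
            raise ValueError(f"unknown parameter {e.param!r}")
    rng = np.random.default_rng(spec.seed)
    bounds = params.bounds()
    mid = bounds.mean(axis=1)
    width = bounds[:, 1] - bounds[:, 0]
    reflex = params.reflex_names()
    out = {}
    for set_id in (1, 2, 3):
        lo, hi = spec.char_ranges[set_id]
        char = rng.uniform(lo, hi, spec.n)
        if set_id == 1:
            speed = char
            sd = np.clip(0.75 - 0.12 * (speed - 1.0)
                         + rng.normal(0, 0.03, spec.n), 0.5, 1.05)
            sl = speed * sd
        elif set_id == 2:
            sl = char
            sd = 0.69 + rng.normal(0, 0.004, spec.n)
            speed = sl / sd
        else:
            sd = char
            sl = 0.72 + rng.normal(0, 0.008, spec.n)
            speed = sl / sd
        effort = np.clip(2.8 + 0.9 * np.abs(speed - 1.05)
                         + rng.normal(0, 0.15, spec.n), 1.5, 3.9)
        ch_std = _standardize(char)

        X = np.tile(params.values, (spec.n, 1))
        for name in reflex:
            i = params.index[name]
            X[:, i] = mid[i] + spec.param_spread * width[i] \
                * rng.standard_normal(spec.n)
        for e in spec.effects:
            if e.set_id != set_id:
                continue
            i = params.index[e.param]
            power = {"linear": 1, "quadratic": 2, "cubic": 3}[e.form]
            base = _standardize(ch_std ** power)
            c = e.correlation
            if spec.exact:
                noise = _orthonormal_noise(rng, ch_std, base)
            else:
                noise = rng.standard_normal(spec.n)
            p_std = c * base + np.sqrt(max(0.0, 1 - c * c)) * noise
            X[:, i] = mid[i] + spec.param_spread * width[i] * p_std

        recs = []
        for k in range(spec.n):
            m = GaitMetrics(
                speed=float(speed[k]), step_length=float(sl[k]),
                step_duration=float(sd[k]), effort=float(effort[k]),
                joint_penalties={"hip": abs(rng.normal(0, 0.08)),
                                 "knee": abs(rng.normal(0, 0.08)),
                                 "ankle": abs(rng.normal(0, 0.5))},
                head_penalty=abs(rng.normal(0, 0.2)), time_sim=15.0,
                events=[], fall=False, usable=True)
            recs.append(SolutionRecord(
                values=np.clip(X[k], bounds[:, 0], bounds[:, 1]),
                metrics=m, cost=0.0, set_id=set_id,
                target=float(char[k]), seed=spec.seed, converged=True))
        out[set_id] = recs
    return out


# ---------------------------------------------------------------------
# synthetic traces
# ---------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Ground truth of one synthetic walking trace.

    Any two of (speed, step_length, step_duration) determine the third;
    supplying all three requires consistency.
    """
    step_length: float = 0.70        # m
    step_duration: float = 0.70      # s
    speed: float | None = None       # m/s
    duration: float = 10.0           # s
    dt: float = 0.01
    first_event: float = 0.5         # s, first heel strike
    n_events: int | None = None      # cap the number of heel strikes
    fall_time: float | None = None
    com_height: float = 0.95         # m
    grf_amplitude: float = 800.0     # N
    stance_fraction: float = 0.6     # of the 2*sd gait cycle
    joint_amplitude_deg: dict = field(default_factory=lambda: {
        "hip": 14.0, "knee": 30.0, "ankle": 10.0})
    joint_offset_deg: dict = field(default_factory=lambda: {
        "hip": 10.0, "knee": 31.0, "ankle": -5.0})
    head_acc: tuple = (0.0, 0.0)     # constant (forward, vertical), m/s^2

    def __post_init__(self):
        if self.speed is None:
            self.speed = self.step_length / self.step_duration
        elif abs(self.speed - self.step_length / self.step_duration) > 1e-9:
            raise ValueError("speed must equal step_length / step_duration")
        if self.first_event >= self.duration:
            raise ValueError("first event after trace end")
        if self.fall_time is not None and self.fall_time > self.duration:
            raise ValueError("fall time after trace end")


def synth_trace(spec: TraceSpec) -> SimulationTrace:
    n = int(round(spec.duration / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    data = np.zeros((n, NCH))
    data[:, CH_INDEX["time"]] = t
    data[:, CH_INDEX["q_pelvis_x"]] = spec.speed * t
    data[:, CH_INDEX["qd_pelvis_x"]] = spec.speed
    com_y = np.full(n, spec.com_height)
    if spec.fall_time is not None:
        com_y[t >= spec.fall_time - 1e-12] = 0.79 * spec.com_height
    data[:, CH_INDEX["com_y"]] = com_y
    data[:, CH_INDEX["com_x"]] = spec.speed * t
    data[:, CH_INDEX["head_ax"]] = spec.head_acc[0]
    data[:, CH_INDEX["head_ay"]] = spec.head_acc[1]

    # heel strikes: alternating feet, contralateral spacing = sd,
    # consecutive contact abscissae spaced by sl
    sd, sl = spec.step_duration, spec.step_length
    events = []
    k = 0
    while True:
        te = spec.first_event + k * sd
        if te > spec.duration - spec.dt:
            break
        if spec.n_events is not None and k >= spec.n_events:
            break
        events.append((te, "r" if k % 2 == 0 else "l",
                       spec.speed * spec.first_event + k * sl))
        k += 1
    stance = spec.stance_fraction * 2.0 * sd
    for foot in ("r", "l"):
        fn = np.zeros(n)
        x = np.zeros(n)
        for te, f, xe in events:
            if f != foot:
                continue
            i0 = int(round(te / spec.dt))
            i1 = min(int(round((te + stance) / spec.dt)), n)
            fn[i0:i1] = spec.grf_amplitude
            x[i0:] = xe
        data[:, CH_INDEX[f"calcn_{foot}_fn"]] = fn
        data[:, CH_INDEX[f"calcn_{foot}_x"]] = x
        data[:, CH_INDEX[f"grf_{foot}_fy"]] = fn

    cycle = 2.0 * sd
    for joint in ("hip", "knee", "ankle"):
        amp = spec.joint_amplitude_deg.get(joint, 0.0) * DEG2RAD
        off = spec.joint_offset_deg.get(joint, 0.0) * DEG2RAD
        for side, shift in (("r", 0.0), ("l", sd)):
            ang = off + amp * np.sin(2 * np.pi * (t - shift) / cycle)
            data[:, CH_INDEX[f"q_{joint}_{side}"]] = ang
    return SimulationTrace(data, dt=spec.dt, time_max=spec.duration)
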