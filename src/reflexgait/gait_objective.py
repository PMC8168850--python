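"""Gait metrics and the seven-component optimization cost.

The cost of one simulated gait is

    cost = p_stability + p_speed + p_sl + p_sd + p_effort + p_joints + p_head

with p_stability = w * (time_max - time_sim)/time_max, absolute-difference
penalties for speed / step length / step duration against their targets
(or target bands), a weighted effort term, and time-averaged exceedance
penalties for the desired joint ranges and head-acceleration bands.

Step events are heel strikes: the calcaneus-sphere vertical force rising
through a 20 N threshold.  Metrics are measured from the second heel
strike onward to discard the launch transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metabolics import MuscleEnergetics, effort as compute_effort
from .trace import SimulationTrace

RAD2DEG = 180.0 / np.pi

#: desired joint ranges in degrees (positive flexion / dorsiflexion)
JOINT_RANGES_DEG = {"hip": (-16.2, 42.0), "knee": (-1.3, 68.2),
                    "ankle": (-27.7, 15.5)}
HEAD_BANDS = {"forward": (-2.45, 2.45), "vertical": (-4.9, 4.9)}  # m/s^2


@dataclass
class ObjectiveConfig:
    time_max: float = 15.0
    termination_ratio: float = 0.8
    speed_target: float | tuple[float, float] | None = None
    sl_target: float | tuple[float, float] | None = None
    sd_target: float | tuple[float, float] | None = None
    joint_ranges: dict = field(default_factory=lambda: dict(JOINT_RANGES_DEG))
    head_bands: dict = field(default_factory=lambda: dict(HEAD_BANDS))
    heel_strike_threshold: float = 20.0     # N
    heel_strike_refractory: float = 0.2     # s

    def __post_init__(self):
        if not self.time_max > 0:
            raise ValueError("time_max must be positive")
        if not 0 < self.termination_ratio < 1:
            raise ValueError("termination ratio must lie in (0, 1)")
        for lo, hi in self.joint_ranges.values():
            if lo >= hi:
                raise ValueError("empty joint range")


@dataclass
class CostWeights:
    """Per-set weights of the seven cost components."""
    stability: float = 100.0
    speed: float = 100.0
    sl: float = 0.0
    sd: float = 0.0
    effort: float = 1.0
    joints: float = 0.1
    head: float = 0.25

    @classmethod
    def for_set(cls, set_id: int) -> "CostWeights":
        if set_id == 1:
            return cls()
        if set_id == 2:
            return cls(sl=1.0, sd=0.0, effort=0.1)
        if set_id == 3:
            return cls(sl=0.0, sd=1.0, effort=0.1)
        raise ValueError("set_id must be 1, 2 or 3")


@dataclass
class StepEvent:
    time: float
    foot: str          # "r" | "l"
    position: float    # fore-aft calcaneus contact abscissa (m)


@dataclass
class GaitMetrics:
    speed: float
    step_length: float
    step_duration: float
    effort: float
    joint_penalties: dict
    head_penalty: float
    time_sim: float
    events: list
    fall: bool
    usable: bool

    def as_dict(self) -> dict:
        d = {"speed": self.speed, "step_length": self.step_length,
             "step_duration": self.step_duration, "effort": self.effort,
             "time_sim": self.time_sim, "fall": self.fall,
             "usable": self.usable, "n_steps": len(self.events),
             "head_penalty": self.head_penalty}
        for j, v in self.joint_penalties.items():
            d[f"penalty_{j}"] = v
        return d


def termination_check(trace: SimulationTrace,
                      config: ObjectiveConfig | None = None):
    """(terminated, time_sim) from the COM-height ratio series.

    The simulation counts as terminated at the first strict crossing
    below ``termination_ratio`` x initial COM height; otherwise
    time_sim = time_max.
    """
    config = config or ObjectiveConfig()
    com_y = trace.col("com_y")
    if com_y[0] <= 0:
        raise ValueError("non-positive initial COM height")
    below = com_y / com_y[0] < config.termination_ratio
    if np.any(below):
        return True, float(trace.time[np.argmax(below)])
    return False, float(config.time_max)


def detect_steps(trace: SimulationTrace,
                 config: ObjectiveConfig | None = None) -> tuple[list, bool]:
    """Heel-strike events (time-ordered) and a usability flag.

    An event fires when a foot's calcaneus vertical force rises through
    the threshold, with a refractory interval guarding against contact
    chatter.  Fewer than two events flags the trace unusable.
    """
    config = config or ObjectiveConfig()
    thr = config.heel_strike_threshold
    events = []
    for foot in ("r", "l"):
        fn = trace.col(f"calcn_{foot}_fn")
        x = trace.col(f"calcn_{foot}_x")
        t = trace.time
        last = -np.inf
        for i in range(1, len(fn)):
            if fn[i - 1] < thr <= fn[i] and t[i] - last >= config.heel_strike_refractory:
                events.append(StepEvent(float(t[i]), foot, float(x[i])))
                last = t[i]
    events.sort(key=lambda e: e.time)
    return events, len(events) >= 2


def _band_penalty(series: np.ndarray, lo: float, hi: float) -> float:
    """Time-averaged exceedance beyond [lo, hi] (same unit as series)."""
    over = np.maximum(series - hi, 0.0) + np.maximum(lo - series, 0.0)
    return float(np.mean(over))


def joint_range_penalties(trace: SimulationTrace,
                          config: ObjectiveConfig) -> dict:
    """Per-joint time-averaged range exceedance in degrees (worse side)."""
    out = {}
    for joint in ("hip", "knee", "ankle"):
        lo, hi = config.joint_ranges[joint]
        worst = 0.0
        for side in ("r", "l"):
            ang = trace.col(f"q_{joint}_{side}") * RAD2DEG
            worst = max(worst, _band_penalty(ang, lo, hi))
        out[joint] = worst
    return out


def head_acceleration_penalty(trace: SimulationTrace,
                              config: ObjectiveConfig) -> float:
    lo_f, hi_f = config.head_bands["forward"]
    lo_v, hi_v = config.head_bands["vertical"]
    return _band_penalty(trace.col("head_ax"), lo_f, hi_f) \
        + _band_penalty(trace.col("head_ay"), lo_v, hi_v)


def measure(trace: SimulationTrace, config: ObjectiveConfig | None = None,
            energetics: MuscleEnergetics | None = None) -> GaitMetrics:
    """Extract GaitMetrics from a trace.

    Speed, step length and step duration are averaged from the second
    heel strike onward; unusable traces (too few steps, or a fall) yield
    fall-flagged metrics with zero step measures.
    """
    config = config or ObjectiveConfig()
    terminated, time_sim = termination_check(trace, config)
    if trace.term_time is not None:
        terminated, time_sim = True, float(trace.term_time)
    fall = terminated or trace.fell
    events, usable = detect_steps(trace, config)
    speed = step_length = step_duration = 0.0
    if usable and len(events) >= 3:
        window = events[1:]
        times = np.array([e.time for e in window])
        pos = np.array([e.position for e in window])
        step_duration = float(np.mean(np.diff(times)))
        step_length = float(np.mean(np.abs(np.diff(pos))))
        t = trace.time
        x = trace.col("q_pelvis_x")
        i0, i1 = np.searchsorted(t, times[0]), np.searchsorted(t, times[-1])
        if t[min(i1, len(t) - 1)] > t[i0]:
            speed = float((x[min(i1, len(t) - 1)] - x[i0])
                          / (t[min(i1, len(t) - 1)] - t[i0]))
    elif usable:
        usable = False
    if not usable:
        # fall back to the whole-trace average speed (the recorded
        # average forward progression) when step events are unusable
        t = trace.time
        if len(t) > 1 and t[-1] > t[0]:
            speed = float(trace.distance / (t[-1] - t[0]))
    eff = np.nan
    if energetics is not None and trace.distance > 0:
        eff = compute_effort(trace, energetics)
    return GaitMetrics(
        speed=speed, step_length=step_length, step_duration=step_duration,
        effort=eff, joint_penalties=joint_range_penalties(trace, config),
        head_penalty=head_acceleration_penalty(trace, config),
        time_sim=min(time_sim, trace.time[-1] + trace.dt) if fall else time_sim,
        events=events, fall=fall, usable=usable and not fall)


def penalty_stability(time_sim: float, config: ObjectiveConfig,
                      w: float) -> float:
    return w * (config.time_max - min(time_sim, config.time_max)) \
        / config.time_max


def _target_penalty(value: float, target, w: float) -> float:
    if target is None or w == 0.0:
        return 0.0
    if np.ndim(target) == 1:
        lo, hi = target
        if lo <= value <= hi:
            return 0.0
        return w * (lo - value if value < lo else value - hi)
    return w * abs(value - float(target))


def penalty_speed(speed, target, w):
    return _target_penalty(speed, target, w)


def penalty_sl(sl, target, w):
    return _target_penalty(sl, target, w)


def penalty_sd(sd, target, w):
    return _target_penalty(sd, target, w)


def penalty_effort(eff: float, w: float) -> float:
    return w * eff if np.isfinite(eff) else 0.0


def penalty_joints(trace: SimulationTrace, config: ObjectiveConfig,
                   w: float) -> float:
    return w * sum(joint_range_penalties(trace, config).values())


def penalty_head(trace: SimulationTrace, config: ObjectiveConfig,
                 w: float) -> float:
    return w * head_acceleration_penalty(trace, config)


def total_cost(components: dict) -> float:
    return float(sum(components.values()))


def evaluate(trace: SimulationTrace, config: ObjectiveConfig,
             weights: CostWeights,
             energetics: MuscleEnergetics | None = None):
    """(metrics, components, cost) of one simulated gait."""
    m = measure(trace, config, energetics)
    components = {
        "stability": penalty_stability(m.time_sim, config, weights.stability),
        "speed": penalty_speed(m.speed, config.speed_target, weights.speed),
        "sl": penalty_sl(m.step_length, config.sl_target, weights.sl),
        "sd": penalty_sd(m.step_duration, config.sd_target, weights.sd),
        "effort": penalty_effort(m.effort, weights.effort),
        "joints": weights.joints * sum(m.joint_penalties.values()),
        "head": weights.head * m.head_penalty,
    }
    return m, components, total_cost(components)
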