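"""Optimization protocols: CMA-ES over the reflex parameter vector.

Three protocol sets are defined: set 1 targets walking speed,
set 2 targets step length under a fixed step-duration band [0.68, 0.72] s,
set 3 targets step duration under a fixed step-length band [0.68, 0.72] m.
Sets 2 and 3 are seeded from the stored best mid-range (1.0 m/s) set-1
solution.  Every evaluated candidate whose simulation completes is logged
as a SolutionRecord, so a single run yields a dataset of gaits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..gait_objective import CostWeights, ObjectiveConfig, evaluate
from ..metabolics import MuscleEnergetics
from ..reflex_controller.params import ReflexParameterSet
from ..simulate import GaitSimulator
from ..solution_analysis import SolutionRecord, cycle_convergence
from ..trace import BLOWUP
from .cmaes import CMAES

FIXED_BAND_SD = (0.68, 0.72)    # s, set 2
FIXED_BAND_SL = (0.68, 0.72)    # m, set 3


@dataclass
class OptimizationProtocol:
    set_id: int
    target_kind: str                 # speed | step_length | step_duration
    target: float
    max_gen: int = 1500
    lam: int = 16
    sigma: float = 1.0
    seed: int = 0
    duration: float = 15.0           # simulated seconds per candidate
    weights: CostWeights | None = None
    bound_penalty: float = 10.0

    def __post_init__(self):
        if self.lam < 2 or self.sigma <= 0:
            raise ValueError("need lambda >= 2 and sigma > 0")
        if self.weights is None:
            self.weights = CostWeights.for_set(self.set_id)

    @classmethod
    def from_yaml(cls, path) -> "OptimizationProtocol":
        """Load a protocol description from a YAML mapping."""
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        weights = data.pop("weights", None)
        proto = cls(**data)
        if weights is not None:
            proto.weights = CostWeights(**weights)
        return proto

    def objective_config(self) -> ObjectiveConfig:
        cfg = ObjectiveConfig(time_max=self.duration)
        if self.target_kind == "speed":
            cfg.speed_target = self.target
        elif self.target_kind == "step_length":
            cfg.sl_target = self.target
            cfg.sd_target = FIXED_BAND_SD
        elif self.target_kind == "step_duration":
            cfg.sd_target = self.target
            cfg.sl_target = FIXED_BAND_SL
        else:
            raise ValueError(f"unknown target kind {self.target_kind!r}")
        # speed penalty stays active in sets 2/3 through the kinematic
        # identity target speed = sl/sd evaluated at the fixed band centre
        if self.set_id == 2:
            cfg.speed_target = self.target / 0.70
        elif self.set_id == 3:
            cfg.speed_target = 0.70 / self.target
        return cfg


@dataclass
class ParameterEncoding:
    """Affine map between the full parameter vector and the search space.

    The optimizer works directly on the free (non-frozen) coordinates;
    per-parameter sampling scales seed the CMA covariance, so sigma = 1
    corresponds to one documented standard step per parameter.  Decoding
    clips to bounds and reports a quadratic out-of-bounds penalty.
    """
    params: ReflexParameterSet
    init: np.ndarray
    frozen: np.ndarray

    @classmethod
    def from_params(cls, params: ReflexParameterSet,
                    init: np.ndarray | None = None,
                    frozen_names: set[str] | None = None):
        init = params.values.copy() if init is None else np.asarray(init, float).copy()
        frozen = np.zeros(len(params), dtype=bool)
        for name in frozen_names or ():
            frozen[params.index[name]] = True
        if frozen.all():
            raise ValueError("every parameter is frozen; nothing to optimize")
        return cls(params, init, frozen)

    @property
    def free(self) -> np.ndarray:
        return ~self.frozen

    def encode(self, x_full: np.ndarray) -> np.ndarray:
        return np.asarray(x_full, float)[self.free]

    def decode(self, z: np.ndarray):
        x = self.init.copy()
        x[self.free] = z
        b = self.params.bounds()
        clipped = np.clip(x, b[:, 0], b[:, 1])
        std = self.params.stds()
        pen = float(np.sum(((x - clipped) / std) ** 2))
        return clipped, pen

    def scales(self) -> np.ndarray:
        return self.params.stds()[self.free]


class GaitObjective:
    """Cost of one parameter vector: simulate, measure, penalize."""

    def __init__(self, simulator: GaitSimulator,
                 protocol: OptimizationProtocol,
                 energetics: MuscleEnergetics | None = None):
        self.sim = simulator
        self.protocol = protocol
        self.config = protocol.objective_config()
        self.energetics = energetics or MuscleEnergetics.from_model(
            simulator.model)

    def __call__(self, values: np.ndarray):
        trace = self.sim.run(values, duration=self.protocol.duration)
        if len(trace) < 2:
            return 1e6, None, None, trace
        metrics, components, cost = evaluate(trace, self.config,
                                             self.protocol.weights,
                                             self.energetics)
        if not np.isfinite(cost):
            cost = 1e6
        return cost, metrics, components, trace


def run_optimization(protocol: OptimizationProtocol,
                     encoding: ParameterEncoding, objective,
                     record_traces: bool = False,
                     convergence_tol_deg: float = 2.0):
    """One CMA-ES run; returns (records, info).

    ``objective`` is a GaitObjective (or any callable with its signature).
    info carries the per-generation best-cost history and best vector.
    """
    es = CMAES(encoding.encode(encoding.init), protocol.sigma,
               lam=protocol.lam, seed=protocol.seed,
               scales=encoding.scales())
    records: list[SolutionRecord] = []
    history = []
    for gen in range(protocol.max_gen):
        Z = es.ask()
        f = np.empty(len(Z))
        for i, z in enumerate(Z):
            x, bpen = encoding.decode(z)
            cost, metrics, components, trace = objective(x)
            f[i] = cost + protocol.bound_penalty * bpen
            if metrics is not None and trace is not None \
                    and trace.status != BLOWUP:
                conv = cycle_convergence(trace, tol_deg=convergence_tol_deg) \
                    if metrics.usable else False
                records.append(SolutionRecord(
                    values=x, metrics=metrics, cost=float(f[i]),
                    set_id=protocol.set_id, target=protocol.target,
                    seed=protocol.seed, generation=gen, converged=conv,
                    trace=trace if record_traces else None))
        es.tell(f)
        history.append(es.best_f)
    x_best, _ = encoding.decode(es.best_x)
    info = {"best_values": x_best, "best_cost": es.best_f,
            "history": history, "protocol": protocol}
    return records, info


def run_set(set_id: int, targets, params: ReflexParameterSet,
            simulator: GaitSimulator, base_values: np.ndarray,
            seeds=None, frozen_names: set[str] | None = None,
            **proto_kwargs):
    """Pooled records over one protocol set (one run per target x seed)."""
    kind = {1: "speed", 2: "step_length", 3: "step_duration"}[set_id]
    if seeds is None:
        seeds = [0]
    pooled, infos = [], []
    for target in targets:
        for seed in seeds:
            proto = OptimizationProtocol(set_id=set_id, target_kind=kind,
                                         target=float(target), seed=seed,
                                         **proto_kwargs)
            enc = ParameterEncoding.from_params(params, init=base_values,
                                               frozen_names=frozen_names)
            obj = GaitObjective(simulator, proto)
            recs, info = run_optimization(proto, enc, obj)
            pooled.extend(recs)
            infos.append(info)
    return pooled, infos


def freeze_masks(params: ReflexParameterSet, key_names: set[str],
                 mode: str, freeze_support: bool = False) -> set[str]:
    """Frozen-parameter names for the key-only / nonkey-only validations.

    key-only: only the key reflex parameters (plus balance, feedforward
    and state parameters) may change; every other reflex entry is frozen.
    nonkey-only: the key reflexes are frozen instead.  ``freeze_support``
    additionally freezes balance + feedforward + state.
    """
    reflex = set(params.reflex_names())
    unknown = key_names - reflex
    if unknown:
        raise ValueError(f"not reflex parameters: {sorted(unknown)}")
    if mode == "key-only":
        frozen = reflex - key_names
    elif mode == "nonkey-only":
        frozen = set(key_names)
    else:
        raise ValueError("mode must be 'key-only' or 'nonkey-only'")
    if freeze_support:
        frozen |= {s.name for s in params.specs
                   if s.category in ("balance", "feedforward", "state")}
    if frozen >= set(params.names):
        raise ValueError("every parameter is frozen; nothing to optimize")
    return frozen


def freeze_and_optimize(protocol: OptimizationProtocol,
                        params: ReflexParameterSet,
                        simulator: GaitSimulator, base_values: np.ndarray,
                        key_names: set[str], mode: str,
                        freeze_support: bool = False):
    """Validation run with the complementary reflex set frozen."""
    frozen = freeze_masks(params, set(key_names), mode, freeze_support)
    enc = ParameterEncoding.from_params(params, init=base_values,
                                        frozen_names=frozen)
    obj = GaitObjective(simulator, protocol)
    return run_optimization(protocol, enc, obj)
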