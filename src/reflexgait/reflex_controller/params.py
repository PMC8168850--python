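"""Reflex parameter table, wiring compilation and delayed signals.

The wiring YAML maps (muscle, pathway, phase group) entries onto named
controller parameters.  ``ReflexParameterSet`` holds the full parameter
vector (reflex gains/offsets, feedforward constants, PD balance constants
and state-machine thresholds); ``CompiledWiring`` is its flat-array view
consumed by the simulation kernel.
"""

from __future__ import annotations

import logging
import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ..model_core.model import MUSCLE_NAMES, NM_SIDE
from .pathways import (force_feedback, length_feedback, pd_balance,
                       velocity_feedback)
from .phases import GaitPhase, N_PHASES

log = logging.getLogger(__name__)

PATHWAY_CODES = {"C": 0, "L": 1, "V": 2, "F": 3, "PD": 4}
CATEGORY_BY_PATHWAY = {"C": "feedforward", "L": "reflex", "V": "reflex",
                       "F": "reflex", "PD": "balance"}

CompiledWiring = namedtuple("CompiledWiring", [
    "ent_muscle", "ent_pathway", "ent_source", "ent_sign", "ent_phases",
    "ent_pa", "ent_pb", "ent_pc",       # parameter indices (-1 unused)
    "delay_samples",                    # per muscle (side-agnostic), samples
    "clamp_lo", "clamp_hi", "tau_act",
    "i_load_thr", "i_d_es_ms", "i_d_s_lp",
])


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    default: float
    lo: float
    hi: float
    std: float
    category: str              # reflex | feedforward | balance | state
    muscle: str | None = None
    pathway: str | None = None
    partner: str | None = None  # the other half of a (kL, l0) stretch pair


class ReflexParameterSet:
    """Named controller parameters with bounds, categories and values."""

    def __init__(self, specs: list[ParameterSpec], config: dict):
        self.specs = specs
        self.index = {s.name: i for i, s in enumerate(specs)}
        self.values = np.array([s.default for s in specs])
        self.config = config
        for s in specs:
            if s.category != "balance" and s.lo > s.hi:
                raise ValueError(f"{s.name}: invalid bounds")

    # -- vector/dict access -------------------------------------------

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self):
        return len(self.specs)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index[name]])

    def __setitem__(self, name: str, v: float):
        self.values[self.index[name]] = v

    def bounds(self) -> np.ndarray:
        return np.array([[s.lo, s.hi] for s in self.specs])

    def stds(self) -> np.ndarray:
        return np.array([s.std for s in self.specs])

    def categories(self) -> list[str]:
        return [s.category for s in self.specs]

    def reflex_names(self) -> list[str]:
        return [s.name for s in self.specs if s.category == "reflex"]

    def stretch_partner(self, name: str) -> str | None:
        return self.specs[self.index[name]].partner

    def replace_values(self, vec) -> "ReflexParameterSet":
        out = ReflexParameterSet(self.specs, self.config)
        out.values = np.asarray(vec, dtype=float).copy()
        return out

    # -- persistence (round-trips bit-exact) --------------------------

    def to_yaml(self, path: str | Path):
        data = {name: float.hex(float(v))
                for name, v in zip(self.names, self.values)}
        with open(path, "w") as fh:
            yaml.safe_dump({"format": "hexfloat", "values": data}, fh)

    def load_values(self, path: str | Path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        vals = data["values"]
        hexfmt = data.get("format") == "hexfloat"
        for name, v in vals.items():
            if name in self.index:
                self[name] = float.fromhex(v) if hexfmt else float(v)
        return self


def default_wiring_path() -> Path:
    return Path(resources.files("reflexgait.reflex_controller")
                / "data" / "wiring.yaml")


def _phase_mask(phases) -> np.ndarray:
    m = np.zeros(N_PHASES, dtype=np.bool_)
    for p in phases:
        m[GaitPhase[p]] = True
    return m


def load_wiring(path: str | Path | None = None):
    """Parse the wiring YAML into (ReflexParameterSet, raw entries, config)."""
    p = Path(path) if path is not None else default_wiring_path()
    with open(p) as fh:
        cfg = yaml.safe_load(fh)

    specs: list[ParameterSpec] = []
    seen = {}

    def add(block, category, muscle=None, pathway=None, partner=None):
        name = block["name"]
        if name in seen:
            return name
        lo, hi = block["bounds"]
        specs.append(ParameterSpec(name, float(block["default"]), float(lo),
                                   float(hi), float(block["std"]), category,
                                   muscle, pathway, partner))
        seen[name] = True
        return name

    entries = []
    for e in cfg["entries"]:
        pw = e["pathway"]
        cat = CATEGORY_BY_PATHWAY[pw]
        rec = {"muscle": e["muscle"], "pathway": pw,
               "source": e.get("source", e["muscle"]),
               "sign": float(e.get("sign", 1)), "phases": list(e["phases"])}
        if pw == "L":
            g, o = e["gain"], e["offset"]
            rec["p_gain"] = add(g, cat, e["muscle"], pw, partner=o["name"])
            rec["p_offset"] = add(o, cat, e["muscle"], pw, partner=g["name"])
        elif pw in ("C", "V", "F"):
            rec["p_gain"] = add(e["param"], cat, e["muscle"], pw)
        elif pw == "PD":
            pass
        entries.append(rec)

    for name in ("KP_BAL", "KV_BAL", "THETA0"):
        add({"name": name, **cfg["balance"][name]}, "balance")
    for name in ("LOAD_THR", "D_ES_MS", "D_S_LP"):
        add({"name": name, **cfg["state"][name]}, "state")

    params = ReflexParameterSet(specs, cfg)
    return params, entries, cfg


def compile_wiring(params: ReflexParameterSet, entries, cfg,
                   dt: float) -> CompiledWiring:
    ne = len(entries)
    ent_muscle = np.zeros(ne, dtype=np.int64)
    ent_pathway = np.zeros(ne, dtype=np.int64)
    ent_source = np.zeros(ne, dtype=np.int64)
    ent_sign = np.zeros(ne)
    ent_phases = np.zeros((ne, N_PHASES), dtype=np.bool_)
    ent_pa = np.full(ne, -1, dtype=np.int64)
    ent_pb = np.full(ne, -1, dtype=np.int64)
    ent_pc = np.full(ne, -1, dtype=np.int64)
    for i, e in enumerate(entries):
        ent_muscle[i] = MUSCLE_NAMES.index(e["muscle"])
        ent_pathway[i] = PATHWAY_CODES[e["pathway"]]
        ent_source[i] = MUSCLE_NAMES.index(e["source"])
        ent_sign[i] = e["sign"]
        ent_phases[i] = _phase_mask(e["phases"])
        if e["pathway"] == "L":
            ent_pa[i] = params.index[e["p_gain"]]
            ent_pb[i] = params.index[e["p_offset"]]
        elif e["pathway"] in ("C", "V", "F"):
            ent_pa[i] = params.index[e["p_gain"]]
        else:  # PD
            ent_pa[i] = params.index["KP_BAL"]
            ent_pb[i] = params.index["KV_BAL"]
            ent_pc[i] = params.index["THETA0"]

    delays = np.zeros(NM_SIDE, dtype=np.int64)
    for mi, name in enumerate(MUSCLE_NAMES):
        group = cfg["muscle_delay_group"][name]
        ms = float(cfg["delays_ms"][group])
        delays[mi] = int(round(ms * 1e-3 / dt))
    lo, hi = cfg["stimulation_clamp"]
    return CompiledWiring(
        ent_muscle=ent_muscle, ent_pathway=ent_pathway, ent_source=ent_source,
        ent_sign=ent_sign, ent_phases=ent_phases, ent_pa=ent_pa,
        ent_pb=ent_pb, ent_pc=ent_pc, delay_samples=delays,
        clamp_lo=float(lo), clamp_hi=float(hi),
        tau_act=float(cfg["tau_activation"]),
        i_load_thr=params.index["LOAD_THR"],
        i_d_es_ms=params.index["D_ES_MS"],
        i_d_s_lp=params.index["D_S_LP"])


class DelayedSignalBuffer:
    """Ring buffer of past samples with nearest-sample delayed reads.

    Samples are pushed at a fixed rate ``dt``; queries at (t - tD) return
    the stored sample nearest that time, or the initial sample before any
    history exists.
    """

    def __init__(self, initial: np.ndarray, dt: float, max_delay: float):
        self.dt = dt
        self.size = int(np.ceil(max_delay / dt)) + 1
        self.initial = np.array(initial, dtype=float, copy=True)
        self.buf = np.tile(self.initial,
                           (self.size,) + (1,) * np.ndim(initial)).reshape(
            (self.size,) + np.shape(initial))
        self.step = -1

    def push(self, sample):
        self.step += 1
        self.buf[self.step % self.size] = sample

    def read_delayed(self, delay: float):
        d = int(round(delay / self.dt))
        if d >= self.size:
            raise ValueError("delay exceeds buffer capacity")
        if self.step < 0:
            raise RuntimeError("buffer empty")
        k = self.step - d
        if k < 0:
            return self.initial.copy()   # before history exists
        return self.buf[k % self.size].copy()


def compose_stimulation(muscle: str, phase: GaitPhase, signals: dict,
                        params: ReflexParameterSet, entries,
                        clamp: tuple[float, float] = (0.01, 1.0)) -> float:
    """Total stimulation for one muscle in one phase (reference path).

    ``signals`` maps source muscle name -> (l~, v~, f~) of the *delayed*
    normalized proprioception, plus "trunk" -> (theta, thetadot).  Only
    pathways wired for (muscle, phase) contribute; an unwired query logs a
    warning and returns the clamped feedforward-only value.
    """
    u = 0.0
    wired = False
    for e in entries:
        if e["muscle"] != muscle or phase.name not in e["phases"]:
            continue
        wired = True
        pw = e["pathway"]
        if pw == "C":
            u += params[e["p_gain"]]
        elif pw == "L":
            l, _, _ = signals[e["source"]]
            u += e["sign"] * length_feedback(params[e["p_gain"]], l,
                                             params[e["p_offset"]])
        elif pw == "V":
            _, v, _ = signals[e["source"]]
            u += e["sign"] * velocity_feedback(params[e["p_gain"]], v)
        elif pw == "F":
            _, _, f = signals[e["source"]]
            u += e["sign"] * force_feedback(params[e["p_gain"]], f)
        elif pw == "PD":
            th, thd = signals["trunk"]
            raw = pd_balance(params["KP_BAL"], params["KV_BAL"], th, thd,
                             params["THETA0"])
            u += max(0.0, e["sign"] * raw)
    if not wired:
        log.warning("no wired pathway for %s in phase %s; feedforward only",
                    muscle, phase.name)
    return float(min(max(u, clamp[0]), clamp[1]))
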