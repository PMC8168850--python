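"""Column-oriented simulation traces.

A :class:`SimulationTrace` wraps one rectangular record array sampled at
the recording rate (default 1 kHz), with named channels for generalized
coordinates/velocities, per-muscle activation/stimulation/force/fiber
kinematics, per-leg phase labels, COM and head kinematics and ground
reaction forces.  Traces round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core.model import COORD_NAMES, MUSCLE_NAMES

_MUS18 = [f"{n}_{s}" for s in ("r", "l") for n in MUSCLE_NAMES]


def _channel_names() -> list[str]:
    names = ["time"]
    names += [f"q_{c}" for c in COORD_NAMES]
    names += [f"qd_{c}" for c in COORD_NAMES]
    for kind in ("act", "stim", "frc", "lce", "vce"):
        names += [f"{kind}_{m}" for m in _MUS18]
    names += ["phase_r", "phase_l", "com_x", "com_y", "head_ax", "head_ay",
              "grf_r_fx", "grf_r_fy", "grf_l_fx", "grf_l_fy",
              "calcn_r_x", "calcn_l_x", "calcn_r_fn", "calcn_l_fn"]
    return names


CHANNELS = _channel_names()
NCH = len(CHANNELS)
CH_INDEX = {n: i for i, n in enumerate(CHANNELS)}

# outcome codes
OK, FELL, BLOWUP = 0, 1, 2


@dataclass
class SimulationTrace:
    """Recorded time series of one forward simulation."""
    data: np.ndarray                  # (n, NCH)
    dt: float                         # recording interval (s)
    status: int = OK
    term_time: float | None = None    # COM-height termination crossing
    time_max: float = 15.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[1] != NCH:
            raise ValueError("trace data must be (n, %d)" % NCH)

    def __len__(self):
        return self.data.shape[0]

    @property
    def fell(self) -> bool:
        return self.status == FELL

    @property
    def time(self) -> np.ndarray:
        return self.data[:, 0]

    def col(self, name: str) -> np.ndarray:
        return self.data[:, CH_INDEX[name]]

    def muscle(self, kind: str, name: str, side: str = "r") -> np.ndarray:
        return self.col(f"{kind}_{name}_{side}")

    @property
    def duration(self) -> float:
        return float(self.time[-1]) if len(self) else 0.0

    @property
    def distance(self) -> float:
        x = self.col("q_pelvis_x")
        return float(x[-1] - x[0]) if len(self) else 0.0

    def foot_vertical_grf(self, side: str) -> np.ndarray:
        return self.col(f"grf_{side}_fy")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=CHANNELS)

    def to_csv(self, path: str | Path):
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# dt={self.dt!r} status={self.status} "
                     f"term_time={self.term_time!r} time_max={self.time_max!r}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimulationTrace":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        meta = dict(kv.split("=", 1) for kv in header[1:].split())
        term = meta["term_time"]
        return cls(df.to_numpy(dtype=float), dt=float(meta["dt"]),
                   status=int(meta["status"]),
                   term_time=None if term == "None" else float(term),
                   time_max=float(meta["time_max"]))
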