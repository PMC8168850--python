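"""Planar 9-DoF musculoskeletal model definition.

The skeleton is a kinematic tree rooted at a 3-DoF planar pelvis-ground
joint (two prismatic + one revolute), with revolute hip, knee and ankle
joints per leg.  The head, arms and trunk are lumped rigidly with the
pelvis (HAT segment); the trunk forward-lean angle used by the balance
controller is the pelvis tilt coordinate.

Generalized coordinates (order fixed throughout the package)::

    q = [pelvis_x, pelvis_y, pelvis_tilt,
         hip_r, knee_r, ankle_r, hip_l, knee_l, ankle_l]

Sign conventions: positive hip flexion, positive knee flexion, positive
ankle dorsiflexion, positive trunk forward lean.  All angles radians.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

NQ = 9                       # generalized coordinates
NB = 9                       # bodies (2 massless virtual + 7 segments)
MUSCLE_NAMES = ("GMAX", "HAMS", "ILPSO", "RF", "VAS", "BFSH", "GAS", "SOL", "TA")
NM_SIDE = len(MUSCLE_NAMES)
NM = 2 * NM_SIDE             # right side first (indices 0-8), then left

# body indices
B_VX, B_VY, B_HAT = 0, 1, 2
B_FEMUR_R, B_SHANK_R, B_FOOT_R = 3, 4, 5
B_FEMUR_L, B_SHANK_L, B_FOOT_L = 6, 7, 8

# joint/coordinate indices
Q_X, Q_Y, Q_TILT = 0, 1, 2
Q_HIP_R, Q_KNEE_R, Q_ANKLE_R = 3, 4, 5
Q_HIP_L, Q_KNEE_L, Q_ANKLE_L = 6, 7, 8

COORD_NAMES = ("pelvis_x", "pelvis_y", "pelvis_tilt",
               "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")

# joint types
JT_REV, JT_PX, JT_PY = 0, 1, 2

PARENT = np.array([-1, 0, 1, 2, 3, 4, 2, 6, 7], dtype=np.int64)
JTYPE = np.array([JT_PX, JT_PY, JT_REV, JT_REV, JT_REV, JT_REV,
                  JT_REV, JT_REV, JT_REV], dtype=np.int64)
# axis sign mapping the anatomical convention onto counterclockwise-positive
# mathematical rotations (x forward, y up)
JSIGN = np.array([1.0, 1.0, -1.0, 1.0, -1.0, 1.0, 1.0, -1.0, 1.0])

_SEG_BODY = {
    ("pelvis", "r"): B_HAT, ("pelvis", "l"): B_HAT,
    ("femur", "r"): B_FEMUR_R, ("femur", "l"): B_FEMUR_L,
    ("shank", "r"): B_SHANK_R, ("shank", "l"): B_SHANK_L,
    ("foot", "r"): B_FOOT_R, ("foot", "l"): B_FOOT_L,
}

# Arrays consumed by the numba kernels.  One flat namedtuple keeps the
# kernel signatures manageable and is supported natively by numba.
ModelArrays = namedtuple("ModelArrays", [
    "parent", "jtype", "jsign", "jpos",          # topology
    "mass", "com", "inertia", "gravity",         # inertial
    "anc",                                       # ancestor mask [NB, NQ]
    "qmin", "qmax", "stop_k", "stop_d", "joint_damping",
    "mus_fmax", "mus_lopt", "mus_lslack", "mus_vmax", "mus_fft",
    "pt_body", "pt_xy", "mus_pt_start",          # muscle via-point paths
    "mus_carm", "mus_L0",                        # constant-arm paths
    "mus_joints",                                # [NM, NQ] spanned-joint mask
    "sph_body", "sph_pos", "sph_radius",
    "contact_k", "contact_c", "contact_mu", "contact_vreg",
    "hill",                                      # hill-curve constants
    "head_point",
])

# hill constant vector layout
H_FLW, H_FVA, H_FVM, H_FVS, H_PSTRAIN, H_PEXP, H_DAMP, H_CLO, H_CHI = range(9)


@dataclass(frozen=True)
class Segment:
    name: str
    mass: float
    length: float
    com: tuple[float, float]
    inertia: float


@dataclass(frozen=True)
class AnthropometricModel:
    """Segment table plus totals; masses sum to ``total_mass`` exactly."""
    total_height: float
    total_mass: float
    segments: dict[str, Segment]

    def __post_init__(self):
        ssum = self.segments["hat"].mass + 2 * (
            self.segments["femur"].mass + self.segments["shank"].mass
            + self.segments["foot"].mass)
        if abs(ssum - self.total_mass) > 1e-9:
            raise ValueError(f"segment masses sum to {ssum}, not {self.total_mass}")
        for s in self.segments.values():
            if s.mass < 0 or s.length <= 0 or s.inertia <= 0:
                raise ValueError(f"non-physical segment {s.name}")


@dataclass(frozen=True)
class MuscleTendonUnit:
    """Rigid-tendon Hill unit; its path is either a via-point polyline or
    constant (cam-like) moment arms per spanned joint (patellar muscles)."""
    name: str
    side: str
    f_max: float
    l_opt: float
    tendon_slack_length: float
    v_max: float
    fast_twitch: float
    path: tuple[tuple[int, float, float], ...] = ()   # (body, x, y) via-points
    arms: tuple[tuple[int, float], ...] = ()          # (coordinate, arm m/rad)
    base_length: float = 0.0

    def __post_init__(self):
        if self.f_max <= 0 or self.l_opt <= 0:
            raise ValueError(f"{self.name}: f_max and l_opt must be positive")
        if len(self.path) < 2 and not self.arms:
            raise ValueError(f"{self.name}: needs a path or moment arms")


@dataclass(frozen=True)
class ContactSphere:
    name: str
    body: int
    pos: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class SystemState:
    """Full mechanical + muscle state at one instant."""
    time: float
    q: np.ndarray                # (9,)
    qd: np.ndarray               # (9,)
    act: np.ndarray              # (18,) activations in [0, 1]
    fiber_length: np.ndarray     # (18,) normalized

    @property
    def trunk_lean(self) -> float:
        # forward-lean angle is a pure function of q
        return float(self.q[Q_TILT])

    @property
    def trunk_lean_rate(self) -> float:
        return float(self.qd[Q_TILT])

    def copy(self) -> "SystemState":
        return SystemState(self.time, self.q.copy(), self.qd.copy(),
                           self.act.copy(), self.fiber_length.copy())


def muscle_index(name: str, side: str) -> int:
    i = MUSCLE_NAMES.index(name)
    return i if side == "r" else i + NM_SIDE


def default_model_path() -> Path:
    return Path(resources.files("reflexgait.model_core") / "data" / "model.yaml")


class PlanarModel:
    """Loaded model: typed views plus the flat arrays the kernels consume."""

    def __init__(self, config: dict):
        self.config = config
        seg = config["segments"]
        total = float(config["total_mass"])
        raw = seg["hat"]["mass"] + 2 * (seg["femur"]["mass"]
                                        + seg["shank"]["mass"] + seg["foot"]["mass"])
        scale = total / raw      # renormalize so masses sum to the stated total
        segs = {
            name: Segment(name, seg[name]["mass"] * scale, seg[name]["length"],
                          tuple(seg[name]["com"]), seg[name]["inertia"])
            for name in ("hat", "femur", "shank", "foot")
        }
        self.skeleton = AnthropometricModel(float(config["total_height"]),
                                            total, segs)
        self.gravity = float(config.get("gravity", 9.81))
        self._build_muscles(config)
        self._build_spheres(config)
        self.arrays = self._build_arrays(config)
        # derive tendon slack lengths from the reference pose (all q zero)
        self._derive_slack(config)

    # -- construction -------------------------------------------------

    def _build_muscles(self, config):
        joint_of = {"r": {"hip": Q_HIP_R, "knee": Q_KNEE_R, "ankle": Q_ANKLE_R},
                    "l": {"hip": Q_HIP_L, "knee": Q_KNEE_L, "ankle": Q_ANKLE_L}}
        self.muscles: list[MuscleTendonUnit] = []
        for side in ("r", "l"):
            for name in MUSCLE_NAMES:
                m = config["muscles"][name]
                path = tuple((_SEG_BODY[(p[0], side)], float(p[1]), float(p[2]))
                             for p in m.get("path", ()))
                arms = tuple((joint_of[side][j], float(a))
                             for j, a in m.get("arms", {}).items())
                self.muscles.append(MuscleTendonUnit(
                    name=name, side=side, f_max=float(m["f_max"]),
                    l_opt=float(m["l_opt"]),
                    tendon_slack_length=0.0,   # derived below
                    v_max=float(m["v_max"]),
                    fast_twitch=float(m["fast_twitch"]), path=path,
                    arms=arms, base_length=float(m.get("base_length", 0.0))))
        # the loop yields the right side first, matching muscle_index

    def _build_spheres(self, config):
        self.spheres: list[ContactSphere] = []
        for side, body in (("r", B_FOOT_R), ("l", B_FOOT_L)):
            for s in config["contact"]["spheres"]:
                self.spheres.append(ContactSphere(
                    f"{s['name']}_{side}", body, tuple(s["pos"]),
                    float(s["radius"])))

    def _build_arrays(self, config) -> ModelArrays:
        segs = self.skeleton.segments
        mass = np.zeros(NB)
        com = np.zeros((NB, 2))
        inertia = np.zeros(NB)
        jpos = np.zeros((NB, 2))
        lf, ls = segs["femur"].length, segs["shank"].length
        for b, s in ((B_HAT, "hat"), (B_FEMUR_R, "femur"), (B_SHANK_R, "shank"),
                     (B_FOOT_R, "foot"), (B_FEMUR_L, "femur"),
                     (B_SHANK_L, "shank"), (B_FOOT_L, "foot")):
            mass[b] = segs[s].mass
            com[b] = segs[s].com
            inertia[b] = segs[s].inertia
        jpos[B_SHANK_R] = jpos[B_SHANK_L] = (0.0, -lf)
        jpos[B_FOOT_R] = jpos[B_FOOT_L] = (0.0, -ls)
        anc = np.zeros((NB, NQ), dtype=np.bool_)
        for b in range(NB):
            j = b
            while j >= 0:
                anc[b, j] = True
                j = PARENT[j]

        lim = config["joint_limits"]
        qmin = np.full(NQ, -np.inf)
        qmax = np.full(NQ, np.inf)
        for jname, idxs in (("hip", (Q_HIP_R, Q_HIP_L)),
                            ("knee", (Q_KNEE_R, Q_KNEE_L)),
                            ("ankle", (Q_ANKLE_R, Q_ANKLE_L))):
            lo, hi = lim[jname]["range"]
            for j in idxs:
                qmin[j], qmax[j] = lo, hi

        pt_body, pt_xy, starts = [], [], [0]
        mus_joints = np.zeros((NM, NQ), dtype=np.bool_)
        mus_carm = np.zeros((NM, NQ))
        mus_L0 = np.zeros(NM)
        for mi, m in enumerate(self.muscles):
            for b, x, y in m.path:
                pt_body.append(b)
                pt_xy.append((x, y))
            starts.append(len(pt_body))
            mus_L0[mi] = m.base_length
            for j, arm in m.arms:
                mus_carm[mi, j] = arm
                mus_joints[mi, j] = True
            # spanned revolute joints: joints on the path between the
            # attachment bodies (exclude the root planar joint: all points
            # move rigidly with it, so it never changes path length)
            bodies = {p[0] for p in m.path}
            for j in range(3, NQ):
                ins = [anc[b, j] for b in bodies]
                if ins and any(ins) and not all(ins):
                    mus_joints[mi, j] = True

        ct = config["contact"]
        h = config["hill"]
        hill = np.array([h["fl_width"], h["fv_shortening_a"],
                         h["fv_lengthening_max"], h["fv_lengthening_slope"],
                         h["passive_strain"], h["passive_exponent"],
                         h["damping"], h["fiber_length_clamp"][0],
                         h["fiber_length_clamp"][1]])

        return ModelArrays(
            parent=PARENT.copy(), jtype=JTYPE.copy(), jsign=JSIGN.copy(),
            jpos=jpos, mass=mass, com=com, inertia=inertia,
            gravity=self.gravity, anc=anc,
            qmin=qmin, qmax=qmax, stop_k=float(lim["stop_stiffness"]),
            stop_d=float(lim["stop_damping"]),
            joint_damping=float(lim["damping"]),
            mus_fmax=np.array([m.f_max for m in self.muscles]),
            mus_lopt=np.array([m.l_opt for m in self.muscles]),
            mus_lslack=np.zeros(NM),
            mus_vmax=np.array([m.v_max for m in self.muscles]),
            mus_fft=np.array([m.fast_twitch for m in self.muscles]),
            pt_body=np.array(pt_body, dtype=np.int64),
            pt_xy=np.array(pt_xy, dtype=np.float64).reshape(-1, 2),
            mus_pt_start=np.array(starts, dtype=np.int64),
            mus_carm=mus_carm, mus_L0=mus_L0,
            mus_joints=mus_joints,
            sph_body=np.array([s.body for s in self.spheres], dtype=np.int64),
            sph_pos=np.array([s.pos for s in self.spheres], dtype=np.float64),
            sph_radius=np.array([s.radius for s in self.spheres]),
            contact_k=float(ct["stiffness"]), contact_c=float(ct["dissipation"]),
            contact_mu=float(ct["friction"]),
            contact_vreg=float(ct["regularization_velocity"]),
            hill=hill,
            head_point=np.array(config["head_point"], dtype=np.float64),
        )

    def _derive_slack(self, config):
        from .dynamics import muscle_lengths_momentarms
        q0 = np.zeros(NQ)
        L, _ = muscle_lengths_momentarms(q0, self.arrays)
        slack = np.zeros(NM)
        new_muscles = []
        for mi, m in enumerate(self.muscles):
            ref = float(config["muscles"][m.name]["ref_norm_fiber_length"])
            slack[mi] = L[mi] - ref * m.l_opt
            if slack[mi] <= 0:
                raise ValueError(f"{m.name}: derived slack length non-positive")
            new_muscles.append(MuscleTendonUnit(
                m.name, m.side, m.f_max, m.l_opt, slack[mi], m.v_max,
                m.fast_twitch, m.path, m.arms, m.base_length))
        self.muscles = new_muscles
        self.arrays.mus_lslack[:] = slack

    # -- convenience --------------------------------------------------

    @property
    def total_mass(self) -> float:
        return self.skeleton.total_mass

    def muscle(self, name: str, side: str = "r") -> MuscleTendonUnit:
        return self.muscles[muscle_index(name, side)]

    def initial_state(self, forward_velocity: float | None = None) -> SystemState:
        """Upright split-stance pose with both feet at ground level."""
        init = self.config["initial_state"]
        pose = init["pose"]
        q = np.zeros(NQ)
        q[Q_TILT] = pose.get("pelvis_tilt", 0.0)
        q[Q_HIP_R], q[Q_KNEE_R], q[Q_ANKLE_R] = (
            pose.get("hip_r", 0.0), pose.get("knee_r", 0.0), pose.get("ankle_r", 0.0))
        q[Q_HIP_L], q[Q_KNEE_L], q[Q_ANKLE_L] = (
            pose.get("hip_l", 0.0), pose.get("knee_l", 0.0), pose.get("ankle_l", 0.0))
        # drop the pelvis until the lowest sphere carries static load
        from .dynamics import sphere_positions
        q[Q_Y] = 1.5
        pos, _ = sphere_positions(q, np.zeros(NQ), self.arrays)
        lowest = np.min(pos[:, 1] - self.arrays.sph_radius)
        q[Q_Y] -= lowest + float(init.get("ground_penetration", 1e-4))
        qd = np.zeros(NQ)
        vx, vy = init["pelvis_velocity"]
        qd[Q_X] = forward_velocity if forward_velocity is not None else vx
        qd[Q_Y] = vy
        act_cfg = init.get("activation", {})
        base = float(act_cfg.get("default", 0.05))
        act = np.full(NM, base)
        for name, v in act_cfg.items():
            if name == "default":
                continue
            for side in ("r", "l"):
                act[muscle_index(name, side)] = float(v)
        from .dynamics import muscle_lengths_momentarms
        L, _ = muscle_lengths_momentarms(q, self.arrays)
        fiber = (L - self.arrays.mus_lslack) / self.arrays.mus_lopt
        return SystemState(0.0, q, qd, act, fiber)


def load_model(path: str | Path | None = None) -> PlanarModel:
    """Load the planar walking model from its YAML definition."""
    p = Path(path) if path is not None else default_model_path()
    with open(p) as fh:
        config = yaml.safe_load(fh)
    return PlanarModel(config)
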