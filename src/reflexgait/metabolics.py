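"""Muscle metabolic energetics and the walking-effort measure.

Implements an Umberger-style muscle energy model (activation/maintenance
heat, shortening/lengthening heat, positive mechanical work) with the
Uchida treatment of eccentric work (negative fiber work is discarded
rather than credited), plus a whole-body basal rate of 1.2 W per kg body
mass.  The effort of a simulation is total energy per distance per body
mass, in J/(kg*m):

    effort = [ integral(basal) + sum_i integral(h_i + w_i) * mass_i ]
             / (distance * mass_model)

Coefficients are pinned here and documented in the methods note; the
fiber-type split is a per-muscle model parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core.model import MUSCLE_NAMES, NM, PlanarModel
from .trace import SimulationTrace

MUSCLE_DENSITY = 1059.7        # kg/m^3
SPECIFIC_TENSION = 2.5e5       # N/m^2
BASAL_RATE = 1.2               # W per kg body mass

# heat-rate coefficients (W/kg muscle), Umberger-style
_AM_SLOW = 25.0                # activation+maintenance, slow-twitch part
_AM_FAST_SCALE = 128.0         # extra per unit fast-twitch fraction
_AEROBIC_SCALE = 1.5           # S, aerobic scaling factor
_VMAX_ST_FRACTION = 0.4        # slow-twitch vmax relative to muscle vmax
_ALPHA_LENGTHEN_FACTOR = 4.0   # lengthening heat per alpha_ST


def muscle_mass(f_max: float, l_opt: float,
                specific_tension: float = SPECIFIC_TENSION,
                density: float = MUSCLE_DENSITY) -> float:
    """Estimated muscle mass (kg): density * PCSA * optimal fiber length."""
    if f_max <= 0 or l_opt <= 0:
        raise ValueError("f_max and l_opt must be positive")
    return density * (f_max / specific_tension) * l_opt


@dataclass
class MuscleEnergetics:
    """Per-muscle constants plus model-level bookkeeping for Eqn-style effort."""
    masses: np.ndarray             # kg, per muscle (18)
    fast_twitch: np.ndarray        # fraction, per muscle
    v_max: np.ndarray              # l_opt/s
    f_max: np.ndarray
    l_opt: np.ndarray
    mass_model: float
    fl_width: float

    @classmethod
    def from_model(cls, model: PlanarModel) -> "MuscleEnergetics":
        ma = model.arrays
        masses = np.array([muscle_mass(f, l)
                           for f, l in zip(ma.mus_fmax, ma.mus_lopt)])
        return cls(masses=masses, fast_twitch=ma.mus_fft.copy(),
                   v_max=ma.mus_vmax.copy(), f_max=ma.mus_fmax.copy(),
                   l_opt=ma.mus_lopt.copy(), mass_model=model.total_mass,
                   fl_width=float(ma.hill[0]))


def heat_rates(a, lce, vce, energetics: MuscleEnergetics, mi=None):
    """Total heat rate (W per kg muscle), vectorized over time.

    a: activation; lce: normalized fiber length; vce: normalized fiber
    velocity in l_opt/s, positive = lengthening.  ``mi`` selects a muscle
    column when array inputs are per-time-sample of one muscle.
    """
    a = np.asarray(a, dtype=float)
    lce = np.asarray(lce, dtype=float)
    vce = np.asarray(vce, dtype=float)
    fft = energetics.fast_twitch if mi is None else energetics.fast_twitch[mi]
    vmax = energetics.v_max if mi is None else energetics.v_max[mi]
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("activation outside [0, 1]")

    d = (lce - 1.0) / energetics.fl_width
    f_iso = np.exp(-d * d)
    A = np.power(np.clip(a, 0.0, 1.0), 0.6)
    am = (_AM_SLOW + _AM_FAST_SCALE * fft) * _AEROBIC_SCALE
    # maintenance portion scales with the force-length curve beyond l_opt
    h_am = np.where(lce > 1.0, am * (0.4 + 0.6 * f_iso) * A, am * A)

    vmax_st = _VMAX_ST_FRACTION * vmax
    alpha_st = 100.0 / vmax_st          # W/kg per (l_opt/s), slow
    alpha_ft = 153.0 / vmax              # fast
    v_short = np.maximum(-vce, 0.0)
    v_len = np.maximum(vce, 0.0)
    a2 = np.power(np.clip(a, 0.0, 1.0), 2.0)
    h_sl = (alpha_st * (1.0 - fft) + alpha_ft * fft) * v_short * a2 \
        + _ALPHA_LENGTHEN_FACTOR * alpha_st * v_len * A
    h = h_am + h_sl
    return np.where(a <= 0.0, 0.0, np.maximum(h, 0.0))


def mechanical_work_rate(force, vce, l_opt, mass):
    """Positive (concentric) fiber work rate, W per kg muscle.

    Negative (eccentric) work is discarded per the Uchida update.
    """
    w = -np.asarray(force, float) * np.asarray(vce, float) * l_opt
    return np.maximum(w, 0.0) / mass


def effort(trace: SimulationTrace, energetics: MuscleEnergetics) -> float:
    """Walking effort in J/(kg*m) from a recorded trace.

    Raises ValueError when the travelled distance is not positive (a
    failed or stationary simulation).
    """
    d = trace.distance
    if d <= 0:
        raise ValueError("non-positive distance: failed or stationary gait")
    t = trace.time
    T = t[-1] - t[0]
    total = BASAL_RATE * energetics.mass_model * T
    for m in range(NM):
        side = "r" if m < 9 else "l"
        name = MUSCLE_NAMES[m % 9]
        a = trace.muscle("act", name, side)
        lce = trace.muscle("lce", name, side)
        vce = trace.muscle("vce", name, side)
        frc = trace.muscle("frc", name, side)
        h = heat_rates(a, lce, vce, energetics, mi=m)
        w = mechanical_work_rate(frc, vce, energetics.l_opt[m],
                                 energetics.masses[m])
        total += np.trapezoid((h + w) * energetics.masses[m], t)
    return float(total / (d * energetics.mass_model))


def per_muscle_energy(trace: SimulationTrace,
                      energetics: MuscleEnergetics):
    """Per-muscle integrated energy (J) breakdown as a DataFrame."""
    import pandas as pd
    t = trace.time
    rows = []
    for m in range(NM):
        side = "r" if m < 9 else "l"
        name = MUSCLE_NAMES[m % 9]
        a = trace.muscle("act", name, side)
        h = heat_rates(a, trace.muscle("lce", name, side),
                       trace.muscle("vce", name, side), energetics, mi=m)
        w = mechanical_work_rate(trace.muscle("frc", name, side),
                                 trace.muscle("vce", name, side),
                                 energetics.l_opt[m], energetics.masses[m])
        rows.append({"muscle": name, "side": side,
                     "mass_kg": energetics.masses[m],
                     "heat_J": float(np.trapezoid(h, t) * energetics.masses[m]),
                     "work_J": float(np.trapezoid(w, t) * energetics.masses[m])})
    return pd.DataFrame(rows)
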