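"""Five-phase gait state machine.

Per leg the cycle is ES -> MS -> PS -> S -> LP -> ES:

* ES (early stance): first double support and early single support,
  entered at heel strike (own foot load rises through the threshold);
* MS (mid-stance): entered when the pelvis has passed the stance ankle;
* PS (pre-swing): second double support, entered when the contralateral
  foot loads;
* S (swing): entered at toe-off (own load falls below threshold);
* LP (landing preparation): late swing, entered when the swing ankle has
  moved sufficiently ahead of the pelvis.

Triggers use the foot load (fraction of body weight) and sagittal
pelvis-ankle distances; the thresholds are controller parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from numba import njit


class GaitPhase(IntEnum):
    ES = 0
    MS = 1
    PS = 2
    S = 3
    LP = 4


N_PHASES = 5


@dataclass
class StateMachineThresholds:
    """Optimizable switching thresholds of the state controller."""
    load_threshold: float = 0.15     # fraction of body weight
    dist_es_ms: float = 0.03         # m, pelvis ahead of stance ankle
    dist_s_lp: float = 0.12          # m, swing ankle ahead of pelvis

    def __post_init__(self):
        if not 0.0 < self.load_threshold < 1.0:
            raise ValueError("load threshold must lie in (0, 1)")


@njit(cache=True)
def phase_step(phase, own_load, contra_load, contra_phase, pelvis_x, ankle_x,
               load_thr, d_es_ms, d_s_lp):
    """One state-machine update for one leg; transitions only along the cycle."""
    if phase == 0:       # ES
        if pelvis_x - ankle_x > d_es_ms:
            return 1
    elif phase == 1:     # MS
        # second double support starts at the contralateral heel strike:
        # the other leg must be freshly loaded (in its early stance)
        if contra_load > load_thr and contra_phase == 0:
            return 2
    elif phase == 2:     # PS
        if own_load < load_thr:
            return 3
    elif phase == 3:     # S
        # landing preparation once the foot is ahead of the pelvis, or
        # immediately on an early ground contact
        if ankle_x - pelvis_x > d_s_lp or own_load > load_thr:
            return 4
    else:                # LP
        if own_load > load_thr:
            return 0
    return phase


@njit(cache=True)
def initial_phase(own_load, pelvis_x, ankle_x, load_thr):
    """Phase assignment at t = 0 from the support/geometry definitions."""
    if own_load > load_thr:
        if pelvis_x - ankle_x > 0.0:
            return 1     # loaded, pelvis past the ankle: mid-stance
        return 0         # loaded, foot ahead: early stance
    if ankle_x - pelvis_x > 0.0:
        return 4         # unloaded, foot ahead: landing preparation
    return 3             # unloaded, foot behind: swing


def phase_transition(phase: GaitPhase, sensors: dict,
                     thresholds: StateMachineThresholds) -> GaitPhase:
    """Single-leg transition from a sensor snapshot.

    ``sensors`` needs: own_load, contra_load (body-weight fractions),
    pelvis_x and ankle_x (m, world fore-aft).
    """
    new = phase_step(int(phase), sensors["own_load"], sensors["contra_load"],
                     int(sensors.get("contra_phase", GaitPhase.S)),
                     sensors["pelvis_x"], sensors["ankle_x"],
                     thresholds.load_threshold, thresholds.dist_es_ms,
                     thresholds.dist_s_lp)
    return GaitPhase(new)
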