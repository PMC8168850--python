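"""Public operations of the mechanical layer.

Conventions: ``muscle_geometry`` moment arms are r_j = -dL/dq_j, so a
positive arm means the muscle generates a positive (flexion/dorsiflexion)
joint torque.  ``hill_force`` follows the classic muscle-mechanics sign
convention of positive fiber velocity = shortening.
"""

from __future__ import annotations

import numpy as np

from . import dynamics as dyn
from .model import (NQ, NM, PlanarModel, SystemState, muscle_index,
                    MUSCLE_NAMES, COORD_NAMES)


def muscle_geometry(q: np.ndarray, muscle: str, model: PlanarModel,
                    side: str = "r"):
    """MTU path length (m) and moment arms (m) for all 9 coordinates.

    Arms are zero for every coordinate the muscle does not span (including
    the root planar joint, which rigidly translates/rotates all points).
    """
    if muscle not in MUSCLE_NAMES:
        raise KeyError(f"unknown muscle {muscle!r}")
    q = np.asarray(q, dtype=float)
    if q.shape != (NQ,) or not np.all(np.isfinite(q)):
        raise ValueError("q must be 9 finite coordinates")
    L, R = dyn.muscle_lengths_momentarms(q, model.arrays)
    mi = muscle_index(muscle, side)
    return float(L[mi]), R[mi].copy()


def hill_force(a: float, l_ce: float, v_ce: float, mtu, model: PlanarModel
               ) -> float:
    """Tendon force (N) of the rigid-tendon Hill unit.

    a: activation in [0, 1]; l_ce: normalized fiber length; v_ce: fiber
    velocity in l_opt/s, positive = shortening.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation outside [0, 1]")
    # kernel convention is lengthening-positive, in v_max units
    v = -float(v_ce) / mtu.v_max
    return float(dyn.hill_tendon_force(float(a), float(l_ce), v, mtu.f_max,
                                       model.arrays.hill))


def hill_force_components(a, l_ce, v_ce, mtu, model):
    """(active, passive) force components in N, without damping."""
    v = -float(v_ce) / mtu.v_max
    fa, fp = dyn.hill_curves(float(a), float(l_ce), v, model.arrays.hill)
    return mtu.f_max * float(fa), mtu.f_max * float(fp)


def contact_force(penetration: float, normal_velocity: float,
                  tangential_velocity: float, sphere, model: PlanarModel):
    """(vertical, horizontal) contact force in N.

    penetration > 0 means the sphere is below ground level;
    normal_velocity is the penetration rate (positive = sinking).
    """
    ma = model.arrays
    ft, fn = dyn.contact_force_1d(float(penetration), float(normal_velocity),
                                  float(tangential_velocity), ma.contact_k,
                                  ma.contact_c, ma.contact_mu, ma.contact_vreg)
    return float(fn), float(ft)


def forward_dynamics(q, qd, tau, model: PlanarModel, q_ext=None,
                     locked=None) -> np.ndarray:
    """Joint accelerations from applied generalized forces.

    ``locked`` is an optional boolean mask of coordinates held fixed
    (their acceleration forced to zero); useful for pinned sub-mechanism
    analyses such as the passive-pendulum check.
    """
    ma = model.arrays
    M = dyn.mass_matrix(q, ma.parent, ma.jtype, ma.jsign, ma.jpos, ma.mass,
                        ma.com, ma.inertia, ma.anc)
    h = dyn.bias_forces(q, qd, ma.parent, ma.jtype, ma.jsign, ma.jpos,
                        ma.mass, ma.com, ma.inertia, ma.anc, ma.gravity)
    rhs = np.asarray(tau, dtype=float) - h
    if q_ext is not None:
        rhs = rhs + q_ext
    if locked is None:
        return np.linalg.solve(M, rhs)
    free = ~np.asarray(locked, dtype=bool)
    qdd = np.zeros(NQ)
    idx = np.where(free)[0]
    qdd[idx] = np.linalg.solve(M[np.ix_(idx, idx)], rhs[idx])
    return qdd


def contact_generalized_forces(q, qd, model: PlanarModel):
    """Total generalized contact force vector plus per-sphere (fx, fy)."""
    ma = model.arrays
    phi, o, w, vo, ax = dyn.forward_kinematics(q, qd, ma.parent, ma.jtype,
                                               ma.jsign, ma.jpos)
    pos, vel = dyn.sphere_positions(q, qd, ma)
    Q = np.zeros(NQ)
    forces = np.zeros((len(ma.sph_radius), 2))
    for s in range(len(ma.sph_radius)):
        b = ma.sph_body[s]
        pen = ma.sph_radius[s] - pos[s, 1]
        # material-point velocity at the bottom of the sphere (rolling)
        vt = vel[s, 0] + w[b] * ma.sph_radius[s]
        ft, fn = dyn.contact_force_1d(pen, -vel[s, 1], vt, ma.contact_k,
                                      ma.contact_c, ma.contact_mu,
                                      ma.contact_vreg)
        forces[s] = (ft, fn)
        if fn == 0.0 and ft == 0.0:
            continue
        px, py = pos[s, 0], pos[s, 1] - ma.sph_radius[s]
        for j in range(NQ):
            if not ma.anc[b, j]:
                continue
            cx, cy = dyn._jac_col(j, px, py, ma.jtype, ma.jsign, o, ax)
            Q[j] += cx * ft + cy * fn
    return Q, forces


def step_dynamics(state: SystemState, stimulations: np.ndarray, dt: float,
                  model: PlanarModel, max_dt: float = 1e-3) -> SystemState:
    """Advance the mechanical state by one semi-implicit Euler step.

    Muscle activation follows the first-order dynamics handled by the
    controller layer (exact exponential update).  Raises RuntimeError on
    integration blow-up (non-finite state), which is distinct from the
    fall/termination condition handled by the objective layer.
    """
    if not (0.0 < dt <= max_dt):
        raise ValueError("dt out of range")
    from ..reflex_controller.pathways import update_activation
    ma = model.arrays
    q, qd = state.q, state.qd
    L, R = dyn.muscle_lengths_momentarms(q, ma)
    vmtu = -(R @ qd)
    lce = (L - ma.mus_lslack) / ma.mus_lopt
    vce = vmtu / ma.mus_lopt / ma.mus_vmax     # lengthening-positive, v_max units
    act = update_activation(state.act, np.asarray(stimulations, float), dt)
    forces = np.empty(NM)
    for mi in range(NM):
        forces[mi] = dyn.hill_tendon_force(act[mi], lce[mi], vce[mi],
                                           ma.mus_fmax[mi], ma.hill)
    tau = R.T @ forces
    tau += dyn.passive_joint_torques(q, qd, ma.qmin, ma.qmax, ma.stop_k,
                                     ma.stop_d, ma.joint_damping)
    q_ext, _ = contact_generalized_forces(q, qd, model)
    qdd = forward_dynamics(q, qd, tau, model, q_ext=q_ext)
    qd_new = qd + qdd * dt
    q_new = q + qd_new * dt
    if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(qd_new))):
        raise RuntimeError("integration blow-up: non-finite state")
    L_new, _ = dyn.muscle_lengths_momentarms(q_new, ma)
    fiber = (L_new - ma.mus_lslack) / ma.mus_lopt
    return SystemState(state.time + dt, q_new, qd_new, act, fiber)
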