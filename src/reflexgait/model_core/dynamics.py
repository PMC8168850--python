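"""Numba kernels for the planar forward dynamics.

Equations of motion are assembled in world coordinates: a recursive
kinematic pass provides body frames and velocities, the joint-space mass
matrix comes from COM Jacobians (M = sum m J^T J + I j_ang^T j_ang), and
Coriolis/gravity bias forces from a Newton-Euler pass with zero joint
acceleration and the gravity base-acceleration trick.  All kernels are
allocation-light and cached.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NQ = 9
NB = 9
NM = 18
JT_REV, JT_PX, JT_PY = 0, 1, 2

# hill vector layout (matches model_core.model)
H_FLW, H_FVA, H_FVM, H_FVS, H_PSTRAIN, H_PEXP, H_DAMP, H_CLO, H_CHI = range(9)


@njit(cache=True, fastmath=False)
def forward_kinematics(q, qd, parent, jtype, jsign, jpos):
    """World angle/origin/velocity per body plus prismatic joint axes."""
    phi = np.zeros(NB)
    o = np.zeros((NB, 2))
    w = np.zeros(NB)
    vo = np.zeros((NB, 2))
    ax = np.zeros((NB, 2))
    for i in range(NB):
        p = parent[i]
        if p < 0:
            phi_p = 0.0
            ox, oy = 0.0, 0.0
            w_p = 0.0
            vx, vy = 0.0, 0.0
        else:
            phi_p = phi[p]
            ox, oy = o[p, 0], o[p, 1]
            w_p = w[p]
            vx, vy = vo[p, 0], vo[p, 1]
        cp, sp = np.cos(phi_p), np.sin(phi_p)
        jx = ox + cp * jpos[i, 0] - sp * jpos[i, 1]
        jy = oy + sp * jpos[i, 0] + cp * jpos[i, 1]
        if jtype[i] == JT_REV:
            s = jsign[i]
            phi[i] = phi_p + s * q[i]
            w[i] = w_p + s * qd[i]
            o[i, 0], o[i, 1] = jx, jy
            vo[i, 0] = vx - w_p * (jy - oy)
            vo[i, 1] = vy + w_p * (jx - ox)
        else:
            if jtype[i] == JT_PX:
                a0, a1 = cp, sp
            else:
                a0, a1 = -sp, cp
            o[i, 0] = jx + a0 * q[i]
            o[i, 1] = jy + a1 * q[i]
            phi[i] = phi_p
            w[i] = w_p
            vo[i, 0] = vx - w_p * (o[i, 1] - oy) + a0 * qd[i]
            vo[i, 1] = vy + w_p * (o[i, 0] - ox) + a1 * qd[i]
            ax[i, 0], ax[i, 1] = a0, a1
    return phi, o, w, vo, ax


@njit(cache=True)
def body_point(b, lx, ly, phi, o):
    c, s = np.cos(phi[b]), np.sin(phi[b])
    return o[b, 0] + c * lx - s * ly, o[b, 1] + s * lx + c * ly


@njit(cache=True)
def body_point_velocity(b, px, py, o, w, vo):
    return vo[b, 0] - w[b] * (py - o[b, 1]), vo[b, 1] + w[b] * (px - o[b, 0])


@njit(cache=True)
def _jac_col(j, px, py, jtype, jsign, o, ax):
    """Velocity of world point (px,py) per unit qd_j (joint j an ancestor)."""
    if jtype[j] == JT_REV:
        s = jsign[j]
        return -s * (py - o[j, 1]), s * (px - o[j, 0])
    return ax[j, 0], ax[j, 1]


@njit(cache=True)
def mass_matrix(q, parent, jtype, jsign, jpos, mass, com, inertia, anc):
    qd0 = np.zeros(NQ)
    phi, o, w, vo, ax = forward_kinematics(q, qd0, parent, jtype, jsign, jpos)
    M = np.zeros((NQ, NQ))
    for b in range(NB):
        if mass[b] <= 0.0:
            continue
        pcx, pcy = body_point(b, com[b, 0], com[b, 1], phi, o)
        jl = np.zeros((2, NQ))
        ja = np.zeros(NQ)
        for j in range(NQ):
            if not anc[b, j]:
                continue
            cx, cy = _jac_col(j, pcx, pcy, jtype, jsign, o, ax)
            jl[0, j] = cx
            jl[1, j] = cy
            if jtype[j] == JT_REV:
                ja[j] = jsign[j]
        for i in range(NQ):
            if not anc[b, i]:
                continue
            for k in range(i, NQ):
                if not anc[b, k]:
                    continue
                v = mass[b] * (jl[0, i] * jl[0, k] + jl[1, i] * jl[1, k]) \
                    + inertia[b] * ja[i] * ja[k]
                M[i, k] += v
                if k != i:
                    M[k, i] += v
    return M


@njit(cache=True)
def bias_forces(q, qd, parent, jtype, jsign, jpos, mass, com, inertia, anc,
                gravity):
    """C(q,qd)qd + g(q): inverse dynamics at qdd = 0 with base accel +g."""
    phi, o, w, vo, ax = forward_kinematics(q, qd, parent, jtype, jsign, jpos)
    alpha = np.zeros(NB)
    ao = np.zeros((NB, 2))
    for i in range(NB):
        p = parent[i]
        if p < 0:
            apx, apy = 0.0, gravity
            al_p = 0.0
            ox, oy = 0.0, 0.0
            w_p = 0.0
            vx, vy = 0.0, 0.0
        else:
            apx, apy = ao[p, 0], ao[p, 1]
            al_p = alpha[p]
            ox, oy = o[p, 0], o[p, 1]
            w_p = w[p]
            vx, vy = vo[p, 0], vo[p, 1]
        rx, ry = o[i, 0] - ox, o[i, 1] - oy
        dvx, dvy = vo[i, 0] - vx, vo[i, 1] - vy
        a0 = apx - al_p * ry - w_p * dvy
        a1 = apy + al_p * rx + w_p * dvx
        if jtype[i] != JT_REV:
            # extra Coriolis from translation along a rotating axis
            a0 += -w_p * (ax[i, 1] * qd[i])
            a1 += w_p * (ax[i, 0] * qd[i])
        ao[i, 0], ao[i, 1] = a0, a1
        alpha[i] = al_p
    tau = np.zeros(NQ)
    for b in range(NB):
        if mass[b] <= 0.0:
            continue
        c, s = np.cos(phi[b]), np.sin(phi[b])
        rcx = c * com[b, 0] - s * com[b, 1]
        rcy = s * com[b, 0] + c * com[b, 1]
        acx = ao[b, 0] - alpha[b] * rcy - w[b] * w[b] * rcx
        acy = ao[b, 1] + alpha[b] * rcx - w[b] * w[b] * rcy
        fx, fy = mass[b] * acx, mass[b] * acy
        tz = inertia[b] * alpha[b]
        pcx, pcy = o[b, 0] + rcx, o[b, 1] + rcy
        for j in range(NQ):
            if not anc[b, j]:
                continue
            cx, cy = _jac_col(j, pcx, pcy, jtype, jsign, o, ax)
            tau[j] += cx * fx + cy * fy
            if jtype[j] == JT_REV:
                tau[j] += jsign[j] * tz
    return tau


@njit(cache=True)
def _muscle_geometry(q, phi, o, ax, jtype, jsign, anc,
                     pt_body, pt_xy, mus_pt_start, mus_carm, mus_L0,
                     mus_joints):
    L = np.zeros(NM)
    R = np.zeros((NM, NQ))
    for mi in range(NM):
        # constant-arm (cam) contribution: L = L0 - sum_j r_j q_j
        L[mi] = mus_L0[mi]
        for j in range(3, NQ):
            if mus_carm[mi, j] != 0.0:
                L[mi] -= mus_carm[mi, j] * q[j]
                R[mi, j] += mus_carm[mi, j]
        p0 = mus_pt_start[mi]
        p1 = mus_pt_start[mi + 1]
        for k in range(p0, p1 - 1):
            ba = pt_body[k]
            bb = pt_body[k + 1]
            ax_, ay_ = body_point(ba, pt_xy[k, 0], pt_xy[k, 1], phi, o)
            bx_, by_ = body_point(bb, pt_xy[k + 1, 0], pt_xy[k + 1, 1], phi, o)
            dx, dy = bx_ - ax_, by_ - ay_
            seg = np.sqrt(dx * dx + dy * dy)
            L[mi] += seg
            if seg < 1e-12:
                continue
            ux, uy = dx / seg, dy / seg
            for j in range(3, NQ):
                if not mus_joints[mi, j]:
                    continue
                dax = day = dbx = dby = 0.0
                if anc[ba, j]:
                    dax, day = _jac_col(j, ax_, ay_, jtype, jsign, o, ax)
                if anc[bb, j]:
                    dbx, dby = _jac_col(j, bx_, by_, jtype, jsign, o, ax)
                # moment arm r_j = -dL/dq_j
                R[mi, j] -= ux * (dbx - dax) + uy * (dby - day)
    return L, R


@njit(cache=True)
def _mlm(q, parent, jtype, jsign, jpos, anc, pt_body, pt_xy, mus_pt_start,
         mus_carm, mus_L0, mus_joints):
    qd0 = np.zeros(NQ)
    phi, o, w, vo, ax = forward_kinematics(q, qd0, parent, jtype, jsign, jpos)
    return _muscle_geometry(q, phi, o, ax, jtype, jsign, anc,
                            pt_body, pt_xy, mus_pt_start, mus_carm, mus_L0,
                            mus_joints)


def muscle_lengths_momentarms(q, ma):
    """MTU path lengths (m) and moment arms r = -dL/dq (m/rad), all muscles."""
    return _mlm(q, ma.parent, ma.jtype, ma.jsign, ma.jpos, ma.anc,
                ma.pt_body, ma.pt_xy, ma.mus_pt_start, ma.mus_carm,
                ma.mus_L0, ma.mus_joints)


@njit(cache=True)
def hill_curves(a, lce, vce, hill):
    """Normalized active and passive force factors of the rigid-tendon unit.

    lce: normalized fiber length (clamped); vce: normalized velocity in
    l_opt/s units scaled by v_max outside, here vce is fiber velocity in
    v_max units (positive = lengthening).  Returns (active, passive) as
    fractions of f_max; active includes a * fl * fv.
    """
    lo, hi = hill[H_CLO], hill[H_CHI]
    l = min(max(lce, lo), hi)
    # Gaussian active force-length
    d = (l - 1.0) / hill[H_FLW]
    fl = np.exp(-d * d)
    # force-velocity: Hill hyperbola for shortening, saturating for
    # lengthening, continuous with slope matching at v = 0
    af = hill[H_FVA]
    fvmax = hill[H_FVM]
    if vce <= 0.0:
        v = -vce          # shortening speed, in v_max units
        if v >= 1.0:
            fv = 0.0
        else:
            fv = (1.0 - v) / (1.0 + v / af)
    else:
        k = hill[H_FVS]
        fv = fvmax - (fvmax - 1.0) / (1.0 + k * vce)
    # exponential passive curve, zero at l <= 1, reaching 1 at 1 + strain
    e0 = hill[H_PSTRAIN]
    kpe = hill[H_PEXP]
    if l > 1.0:
        fp = (np.exp(kpe * (l - 1.0) / e0) - 1.0) / (np.exp(kpe) - 1.0)
    else:
        fp = 0.0
    return a * fl * fv, fp


@njit(cache=True)
def hill_tendon_force(a, lce, vce_norm_vmax, fmax, hill):
    """Total tendon force (N); never negative."""
    fa, fp = hill_curves(a, lce, vce_norm_vmax, hill)
    # small parallel viscous damping (resists fiber velocity) improves
    # robustness against contact chatter; clamped so force stays >= 0
    f = fmax * (fa + fp + hill[H_DAMP] * vce_norm_vmax)
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=True)
def contact_force_1d(pen, pen_rate, vt, k, c, mu, vreg):
    """Hunt-Crossley normal force + regularized Coulomb friction.

    pen: penetration depth (m, >0 in contact); pen_rate: d(pen)/dt;
    vt: tangential velocity of the contact material point.
    Returns (fx, fy) acting on the body at the contact point.
    """
    if pen <= 0.0:
        return 0.0, 0.0
    fn = k * pen ** 1.5 * (1.0 + c * pen_rate)
    if fn < 0.0:
        fn = 0.0
    s = vt / vreg
    if s > 1.0:
        s = 1.0
    elif s < -1.0:
        s = -1.0
    ft = -mu * fn * s
    return ft, fn


@njit(cache=True)
def _sphere_pos_vel(q, qd, parent, jtype, jsign, jpos, sph_body, sph_pos):
    phi, o, w, vo, ax = forward_kinematics(q, qd, parent, jtype, jsign, jpos)
    ns = sph_body.shape[0]
    pos = np.zeros((ns, 2))
    vel = np.zeros((ns, 2))
    for s in range(ns):
        b = sph_body[s]
        px, py = body_point(b, sph_pos[s, 0], sph_pos[s, 1], phi, o)
        vx, vy = body_point_velocity(b, px, py, o, w, vo)
        pos[s, 0], pos[s, 1] = px, py
        vel[s, 0], vel[s, 1] = vx, vy
    return pos, vel


def sphere_positions(q, qd, ma):
    return _sphere_pos_vel(q, qd, ma.parent, ma.jtype, ma.jsign, ma.jpos,
                           ma.sph_body, ma.sph_pos)


@njit(cache=True)
def com_position(q, parent, jtype, jsign, jpos, mass, com):
    qd0 = np.zeros(NQ)
    phi, o, w, vo, ax = forward_kinematics(q, qd0, parent, jtype, jsign, jpos)
    cx = cy = m = 0.0
    for b in range(NB):
        if mass[b] <= 0.0:
            continue
        px, py = body_point(b, com[b, 0], com[b, 1], phi, o)
        cx += mass[b] * px
        cy += mass[b] * py
        m += mass[b]
    return cx / m, cy / m


@njit(cache=True)
def mechanical_energy(q, qd, parent, jtype, jsign, jpos, mass, com, inertia,
                      anc, gravity):
    M = mass_matrix(q, parent, jtype, jsign, jpos, mass, com, inertia, anc)
    T = 0.0
    for i in range(NQ):
        for k in range(NQ):
            T += 0.5 * qd[i] * M[i, k] * qd[k]
    phi, o, w, vo, ax = forward_kinematics(q, qd, parent, jtype, jsign, jpos)
    V = 0.0
    for b in range(NB):
        if mass[b] <= 0.0:
            continue
        px, py = body_point(b, com[b, 0], com[b, 1], phi, o)
        V += mass[b] * gravity * py
    return T + V


@njit(cache=True)
def passive_joint_torques(q, qd, qmin, qmax, stop_k, stop_d, joint_damping):
    tau = np.zeros(NQ)
    for j in range(3, NQ):
        tau[j] -= joint_damping * qd[j]
        if q[j] > qmax[j]:
            tau[j] -= stop_k * (q[j] - qmax[j])
            if qd[j] > 0.0:
                tau[j] -= stop_d * qd[j]
        elif q[j] < qmin[j]:
            tau[j] -= stop_k * (q[j] - qmin[j])
            if qd[j] < 0.0:
                tau[j] -= stop_d * qd[j]
    return tau
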