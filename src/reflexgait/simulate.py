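"""Forward gait simulation: model + reflex controller -> trace.

The whole rollout (controller sampling, activation dynamics, muscle and
contact forces, equations of motion, semi-implicit Euler integration at a
fixed 1e-4 s step) runs in one compiled kernel; traces are recorded at a
coarser rate (default 1 kHz).  The simulation stops early when the COM
height drops below the termination ratio of its initial value (a fall) or
when the state stops being finite (an integration failure).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model_core import dynamics as dyn
from .model_core.model import NM, NQ, PlanarModel, load_model
from .reflex_controller.params import (ReflexParameterSet, compile_wiring,
                                       load_wiring)
from .reflex_controller.phases import initial_phase, phase_step
from .trace import BLOWUP, FELL, NCH, OK, SimulationTrace

NM_SIDE = 9
# sphere indexing: right foot 0..2, left foot 3..5 (calcaneus first)
_CALCN_R, _CALCN_L = 0, 3


@njit(cache=True)
def _rollout(q0, qd0, act0, dt, n_steps, stride, term_ratio,
             parent, jtype, jsign, jpos, mass, com, inertia, gravity, anc,
             qmin, qmax, stop_k, stop_d, joint_damping,
             mus_fmax, mus_lopt, mus_lslack, mus_vmax,
             pt_body, pt_xy, mus_pt_start, mus_carm, mus_L0, mus_joints,
             sph_body, sph_pos, sph_radius, ck, cc, cmu, cvreg,
             hill, head_point,
             ent_muscle, ent_pathway, ent_source, ent_sign, ent_phases,
             ent_pa, ent_pb, ent_pc, delay_samples, clamp_lo, clamp_hi,
             tau_act, i_load_thr, i_d_es_ms, i_d_s_lp, pvals, body_weight):
    ne = ent_muscle.shape[0]
    ns = sph_body.shape[0]
    rb = 0
    for m in range(NM_SIDE):
        if delay_samples[m] + 1 > rb:
            rb = delay_samples[m] + 1
    bl = np.zeros((rb, NM))
    bv = np.zeros((rb, NM))
    bf = np.zeros((rb, NM))
    bth = np.zeros(rb)
    bthd = np.zeros(rb)

    q = q0.copy()
    qd = qd0.copy()
    act = act0.copy()
    f_prev = np.zeros(NM)

    # initial proprioception and buffer prefill
    phi, o, w, vo, ax = dyn.forward_kinematics(q, qd, parent, jtype, jsign, jpos)
    L, R = dyn._muscle_geometry(q, phi, o, ax, jtype, jsign, anc, pt_body,
                                pt_xy, mus_pt_start, mus_carm, mus_L0,
                                mus_joints)
    for m in range(NM):
        lce = (L[m] - mus_lslack[m]) / mus_lopt[m]
        f_prev[m] = dyn.hill_tendon_force(act[m], lce, 0.0, mus_fmax[m], hill) \
            / mus_fmax[m]
        for k in range(rb):
            bl[k, m] = lce
            bf[k, m] = f_prev[m]
    for k in range(rb):
        bth[k] = q[2]
        bthd[k] = qd[2]

    # initial COM height and phases
    cx0, cy0 = dyn.com_position(q, parent, jtype, jsign, jpos, mass, com)
    load_thr = pvals[i_load_thr]
    # foot loads at t0
    pos, vel = dyn._sphere_pos_vel(q, qd, parent, jtype, jsign, jpos,
                                   sph_body, sph_pos)
    load_r = load_l = 0.0
    for s in range(ns):
        pen = sph_radius[s] - pos[s, 1]
        if pen > 0.0:
            fn = ck * pen ** 1.5
            if s < 3:
                load_r += fn
            else:
                load_l += fn
    load_r /= body_weight
    load_l /= body_weight
    ph_r = initial_phase(load_r, q[0], o[5, 0], load_thr)
    ph_l = initial_phase(load_l, q[0], o[8, 0], load_thr)

    n_rec = n_steps // stride + 1
    rec = np.zeros((n_rec, NCH))
    i_rec = 0
    status = 0
    term_time = -1.0
    hvx_prev = 0.0
    hvy_prev = 0.0
    have_hv = False

    for step in range(n_steps):
        t = step * dt
        phi, o, w, vo, ax = dyn.forward_kinematics(q, qd, parent, jtype,
                                                   jsign, jpos)
        L, R = dyn._muscle_geometry(q, phi, o, ax, jtype, jsign, anc, pt_body,
                                    pt_xy, mus_pt_start, mus_carm, mus_L0,
                                    mus_joints)
        lce = np.empty(NM)
        vtil = np.empty(NM)
        for m in range(NM):
            lce[m] = (L[m] - mus_lslack[m]) / mus_lopt[m]
            v = 0.0
            for j in range(3, NQ):
                if mus_joints[m, j]:
                    v -= R[m, j] * qd[j]
            vtil[m] = v / mus_lopt[m]

        # contact
        q_ext = np.zeros(NQ)
        grf = np.zeros(4)           # r_fx, r_fy, l_fx, l_fy
        calcn_fn = np.zeros(2)
        pos, vel = dyn._sphere_pos_vel(q, qd, parent, jtype, jsign, jpos,
                                       sph_body, sph_pos)
        for s in range(ns):
            b = sph_body[s]
            pen = sph_radius[s] - pos[s, 1]
            vt = vel[s, 0] + w[b] * sph_radius[s]
            ft, fn = dyn.contact_force_1d(pen, -vel[s, 1], vt, ck, cc, cmu,
                                          cvreg)
            if fn == 0.0 and ft == 0.0:
                continue
            px, py = pos[s, 0], pos[s, 1] - sph_radius[s]
            for j in range(NQ):
                if anc[b, j]:
                    cxj, cyj = dyn._jac_col(j, px, py, jtype, jsign, o, ax)
                    q_ext[j] += cxj * ft + cyj * fn
            if s < 3:
                grf[0] += ft
                grf[1] += fn
                if s == _CALCN_R:
                    calcn_fn[0] = fn
            else:
                grf[2] += ft
                grf[3] += fn
                if s == _CALCN_L:
                    calcn_fn[1] = fn
        load_r = grf[1] / body_weight
        load_l = grf[3] / body_weight

        # push proprioception (current lengths/velocities, last-step force)
        kb = step % rb
        for m in range(NM):
            bl[kb, m] = lce[m]
            bv[kb, m] = vtil[m]
            bf[kb, m] = f_prev[m]
        bth[kb] = q[2]
        bthd[kb] = qd[2]

        # state machine
        d_es_ms = pvals[i_d_es_ms]
        d_s_lp = pvals[i_d_s_lp]
        load_thr = pvals[i_load_thr]
        ph_r_new = phase_step(ph_r, load_r, load_l, ph_l, q[0], o[5, 0],
                              load_thr, d_es_ms, d_s_lp)
        ph_l_new = phase_step(ph_l, load_l, load_r, ph_r, q[0], o[8, 0],
                              load_thr, d_es_ms, d_s_lp)
        ph_r, ph_l = ph_r_new, ph_l_new

        # compose stimulations
        u = np.zeros(NM)
        for leg in range(2):
            ph = ph_r if leg == 0 else ph_l
            off = NM_SIDE * leg
            for e in range(ne):
                if not ent_phases[e, ph]:
                    continue
                m = ent_muscle[e] + off
                d = delay_samples[ent_muscle[e]]
                k = step - d
                if k < 0:
                    k = 0
                kd = k % rb
                pw = ent_pathway[e]
                if pw == 0:
                    u[m] += pvals[ent_pa[e]]
                elif pw == 1:
                    src = ent_source[e] + off
                    x = bl[kd, src] - pvals[ent_pb[e]]
                    if x > 0.0:
                        u[m] += ent_sign[e] * pvals[ent_pa[e]] * x
                elif pw == 2:
                    src = ent_source[e] + off
                    v = bv[kd, src]
                    if v > 0.0:
                        u[m] += ent_sign[e] * pvals[ent_pa[e]] * v
                elif pw == 3:
                    src = ent_source[e] + off
                    u[m] += ent_sign[e] * pvals[ent_pa[e]] * bf[kd, src]
                else:
                    raw = pvals[ent_pa[e]] * (bth[kd] - pvals[ent_pc[e]]) \
                        + pvals[ent_pb[e]] * bthd[kd]
                    val = ent_sign[e] * raw
                    if val > 0.0:
                        u[m] += val
        for m in range(NM):
            if u[m] < clamp_lo:
                u[m] = clamp_lo
            elif u[m] > clamp_hi:
                u[m] = clamp_hi

        # activation dynamics (exact exponential)
        decay = np.exp(-dt / tau_act)
        for m in range(NM):
            act[m] = u[m] + (act[m] - u[m]) * decay

        # muscle forces and joint torques
        forces = np.empty(NM)
        for m in range(NM):
            vv = vtil[m] / mus_vmax[m]
            forces[m] = dyn.hill_tendon_force(act[m], lce[m], vv,
                                              mus_fmax[m], hill)
            f_prev[m] = forces[m] / mus_fmax[m]
        tau = dyn.passive_joint_torques(q, qd, qmin, qmax, stop_k, stop_d,
                                        joint_damping)
        for m in range(NM):
            for j in range(3, NQ):
                if mus_joints[m, j]:
                    tau[j] += R[m, j] * forces[m]

        # head kinematics
        hx, hy = dyn.body_point(2, head_point[0], head_point[1], phi, o)
        hvx, hvy = dyn.body_point_velocity(2, hx, hy, o, w, vo)
        if have_hv:
            hax = (hvx - hvx_prev) / dt
            hay = (hvy - hvy_prev) / dt
        else:
            hax = hay = 0.0
            have_hv = True
        hvx_prev, hvy_prev = hvx, hvy

        # COM for termination
        cx, cy = dyn.com_position(q, parent, jtype, jsign, jpos, mass, com)

        if step % stride == 0:
            r = rec[i_rec]
            r[0] = t
            for j in range(NQ):
                r[1 + j] = q[j]
                r[10 + j] = qd[j]
            for m in range(NM):
                r[19 + m] = act[m]
                r[37 + m] = u[m]
                r[55 + m] = forces[m]
                r[73 + m] = lce[m]
                r[91 + m] = vtil[m]
            r[109] = ph_r
            r[110] = ph_l
            r[111] = cx
            r[112] = cy
            r[113] = hax
            r[114] = hay
            r[115] = grf[0]
            r[116] = grf[1]
            r[117] = grf[2]
            r[118] = grf[3]
            r[119] = pos[_CALCN_R, 0]
            r[120] = pos[_CALCN_L, 0]
            r[121] = calcn_fn[0]
            r[122] = calcn_fn[1]
            i_rec += 1

        if cy / cy0 < term_ratio:
            status = 1
            term_time = t
            break

        # dynamics and integration
        M = dyn.mass_matrix(q, parent, jtype, jsign, jpos, mass, com,
                            inertia, anc)
        h = dyn.bias_forces(q, qd, parent, jtype, jsign, jpos, mass, com,
                            inertia, anc, gravity)
        qdd = np.linalg.solve(M, tau + q_ext - h)
        ok = True
        for j in range(NQ):
            qd[j] += qdd[j] * dt
            q[j] += qd[j] * dt
            if not np.isfinite(q[j]):
                ok = False
        if not ok:
            status = 2
            term_time = t
            break

    return rec[:i_rec], status, term_time, q, qd, act


class GaitSimulator:
    """Reusable simulator binding a model, a wiring table and rates."""

    def __init__(self, model: PlanarModel | None = None,
                 wiring_path=None, dt: float = 1e-4, record_dt: float = 1e-3,
                 time_max: float = 15.0, term_ratio: float = 0.8):
        self.model = model if model is not None else load_model()
        self.dt = dt
        self.stride = max(1, int(round(record_dt / dt)))
        self.time_max = time_max
        self.term_ratio = term_ratio
        self.params, self.entries, self.cfg = load_wiring(wiring_path)
        self.wiring = compile_wiring(self.params, self.entries, self.cfg, dt)
        self.body_weight = self.model.total_mass * self.model.gravity

    def run(self, values: np.ndarray | None = None,
            duration: float | None = None,
            forward_velocity: float | None = None) -> SimulationTrace:
        """Simulate with the given parameter vector (defaults if None)."""
        pvals = self.params.values if values is None \
            else np.asarray(values, dtype=float)
        if pvals.shape != self.params.values.shape:
            raise ValueError("parameter vector has wrong length")
        dur = self.time_max if duration is None else duration
        n_steps = int(round(dur / self.dt))
        st = self.model.initial_state(forward_velocity=forward_velocity)
        ma = self.model.arrays
        cw = self.wiring
        rec, status, term_time, q, qd, act = _rollout(
            st.q, st.qd, st.act, self.dt, n_steps, self.stride,
            self.term_ratio,
            ma.parent, ma.jtype, ma.jsign, ma.jpos, ma.mass, ma.com,
            ma.inertia, ma.gravity, ma.anc, ma.qmin, ma.qmax, ma.stop_k,
            ma.stop_d, ma.joint_damping, ma.mus_fmax, ma.mus_lopt,
            ma.mus_lslack, ma.mus_vmax, ma.pt_body, ma.pt_xy,
            ma.mus_pt_start, ma.mus_carm, ma.mus_L0, ma.mus_joints,
            ma.sph_body, ma.sph_pos,
            ma.sph_radius, ma.contact_k, ma.contact_c, ma.contact_mu,
            ma.contact_vreg, ma.hill, ma.head_point,
            cw.ent_muscle, cw.ent_pathway, cw.ent_source, cw.ent_sign,
            cw.ent_phases, cw.ent_pa, cw.ent_pb, cw.ent_pc,
            cw.delay_samples, cw.clamp_lo, cw.clamp_hi, cw.tau_act,
            cw.i_load_thr, cw.i_d_es_ms, cw.i_d_s_lp, pvals,
            self.body_weight)
        return SimulationTrace(rec, dt=self.dt * self.stride, status=status,
                               term_time=None if term_time < 0 else term_time,
                               time_max=dur,
                               meta={"duration": dur})


_DEFAULT: GaitSimulator | None = None


def default_simulator() -> GaitSimulator:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GaitSimulator()
    return _DEFAULT


def simulate(values=None, duration=None, **kwargs) -> SimulationTrace:
    """One-call forward simulation with the default model and wiring."""
    if kwargs:
        return GaitSimulator(**kwargs).run(values, duration)
    return default_simulator().run(values, duration)
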