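"""Mechanical layer: skeleton invariants, muscle geometry, Hill curves,
contact law and the integrator's physical sanity."""

import numpy as np
import pytest
import yaml

from reflexgait.model_core import (NQ, PlanarModel, contact_force,
                                   forward_dynamics, hill_force,
                                   hill_force_components, load_model,
                                   muscle_geometry, step_dynamics,
                                   MUSCLE_NAMES)
from reflexgait.model_core import dynamics as dyn
from reflexgait.model_core.model import default_model_path


def test_segment_masses_sum_to_total(model):
    segs = model.skeleton.segments
    total = segs["hat"].mass + 2 * (segs["femur"].mass + segs["shank"].mass
                                    + segs["foot"].mass)
    assert abs(total - 75.16) < 1e-9
    assert model.skeleton.total_height == 1.8


def test_nine_generalized_coordinates(model):
    assert NQ == 9
    st = model.initial_state()
    assert st.q.shape == (9,) and st.qd.shape == (9,)
    assert np.all(st.act >= 0) and np.all(st.act <= 1)


def test_uniarticular_muscle_has_zero_arm_on_nonspanned_joint(model):
    _, arms = muscle_geometry(np.zeros(9), "SOL", model)
    assert arms[3] == 0.0       # hip
    assert arms[4] == 0.0       # knee
    assert arms[5] != 0.0       # ankle


def test_unknown_muscle_and_bad_coordinates_raise(model):
    with pytest.raises(KeyError):
        muscle_geometry(np.zeros(9), "PECS", model)
    q = np.zeros(9)
    q[3] = np.nan
    with pytest.raises(ValueError):
        muscle_geometry(q, "SOL", model)


def test_moment_arms_match_finite_differences(model, rng):
    """r_j = -dL/dq_j for every muscle over random poses."""
    h = 1e-6
    for _ in range(1000):
        q = rng.normal(0.0, 0.4, 9)
        L, R = dyn.muscle_lengths_momentarms(q, model.arrays)
        j = int(rng.integers(3, 9))
        qp, qm = q.copy(), q.copy()
        qp[j] += h
        qm[j] -= h
        Lp, _ = dyn.muscle_lengths_momentarms(qp, model.arrays)
        Lm, _ = dyn.muscle_lengths_momentarms(qm, model.arrays)
        fd = -(Lp - Lm) / (2 * h)
        assert np.all(np.abs(fd - R[:, j]) < 1e-6)


def _brute_force_polyline_length(model, q, mi):
    """Independent path walker: world FK by explicit rotation chains."""
    ma = model.arrays

    def world(b, p):
        # walk up the tree accumulating rotations/translations
        chain = []
        j = b
        while j >= 0:
            chain.append(j)
            j = ma.parent[j]
        x = np.array(p, dtype=float)
        for j in chain:
            if ma.jtype[j] == 0:
                ang = ma.jsign[j] * q[j]
                c, s = np.cos(ang), np.sin(ang)
                x = np.array([c * x[0] - s * x[1], s * x[0] + c * x[1]])
                x = x + ma.jpos[j]
            elif ma.jtype[j] == 1:
                x = x + ma.jpos[j] + np.array([q[j], 0.0])
            else:
                x = x + ma.jpos[j] + np.array([0.0, q[j]])
        return x

    p0, p1 = ma.mus_pt_start[mi], ma.mus_pt_start[mi + 1]
    pts = [world(ma.pt_body[k], ma.pt_xy[k]) for k in range(p0, p1)]
    return sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:]))


@pytest.fixture(scope="module")
def via_point_model():
    """Model variant with one muscle on an explicit via-point polyline."""
    with open(default_model_path()) as fh:
        cfg = yaml.safe_load(fh)
    cfg["muscles"]["GMAX"] = {
        "f_max": 1944.0, "l_opt": 0.157, "v_max": 10.0, "fast_twitch": 0.45,
        "ref_norm_fiber_length": 1.0,
        "path": [["pelvis", -0.095, 0.070], ["femur", -0.040, -0.190]]}
    return PlanarModel(cfg)


def test_via_point_length_matches_brute_force_walker(via_point_model, rng):
    model = via_point_model
    for pose in [np.zeros(9)] + [rng.normal(0, 0.3, 9) for _ in range(10)]:
        L, _ = muscle_geometry(pose, "GMAX", model)
        Lb = _brute_force_polyline_length(
            model, pose, MUSCLE_NAMES.index("GMAX"))
        assert L == pytest.approx(Lb, abs=1e-12)


def test_via_point_moment_arm_matches_finite_difference(via_point_model):
    model = via_point_model
    q = np.zeros(9)
    h = 1e-6
    _, arms = muscle_geometry(q, "GMAX", model)
    qp, qm = q.copy(), q.copy()
    qp[3] += h
    qm[3] -= h
    Lp, _ = muscle_geometry(qp, "GMAX", model)
    Lm, _ = muscle_geometry(qm, "GMAX", model)
    assert arms[3] == pytest.approx(-(Lp - Lm) / (2 * h), abs=1e-6)


class TestHillForce:
    def test_isometric_at_optimal_length(self, model):
        mtu = model.muscle("VAS")
        fa, fp = hill_force_components(1.0, 1.0, 0.0, mtu, model)
        assert fa == pytest.approx(mtu.f_max, rel=1e-12)
        assert fp == 0.0

    def test_maximal_shortening_kills_active_force(self, model):
        mtu = model.muscle("VAS")
        fa, _ = hill_force_components(1.0, 1.0, mtu.v_max, mtu, model)
        assert fa == 0.0

    def test_passive_curve_hand_value(self, model):
        # exponential passive curve at 1.2 l_opt: (e^(k*0.2/e0)-1)/(e^k-1)
        mtu = model.muscle("SOL")
        kpe, e0 = 4.0, 0.6
        expected = mtu.f_max * (np.exp(kpe * 0.2 / e0) - 1) / (np.exp(kpe) - 1)
        _, fp = hill_force_components(0.0, 1.2, 0.0, mtu, model)
        assert fp == pytest.approx(expected, rel=1e-12)

    def test_force_nonnegative_and_continuous(self, model, rng):
        mtu = model.muscle("GAS")
        prev = None
        for v in np.linspace(-mtu.v_max, mtu.v_max, 801):
            f = hill_force(0.5, 1.1, v, mtu, model)
            assert f >= 0.0
            if prev is not None:
                assert abs(f - prev) < mtu.f_max * 0.02
            prev = f

    def test_activation_outside_unit_interval_rejected(self, model):
        with pytest.raises(ValueError):
            hill_force(1.5, 1.0, 0.0, model.muscle("VAS"), model)


class TestContact:
    def test_no_contact_no_force(self, model):
        assert contact_force(-0.01, 0.0, 0.0, model.spheres[0], model) == (0.0, 0.0)

    def test_hunt_crossley_hand_value(self, model):
        k = model.arrays.contact_k
        fn, ft = contact_force(0.005, 0.0, 0.0, model.spheres[0], model)
        assert fn == pytest.approx(k * 0.005 ** 1.5, rel=1e-12)
        assert ft == 0.0

    def test_friction_cone_saturates_exactly(self, model):
        fn, ft = contact_force(0.005, 0.0, 10.0, model.spheres[0], model)
        assert abs(ft) == pytest.approx(model.arrays.contact_mu * fn, rel=1e-12)

    def test_friction_bounded_by_cone(self, model, rng):
        for _ in range(100):
            pen = rng.uniform(0, 0.01)
            fn, ft = contact_force(pen, rng.uniform(-1, 1),
                                   rng.uniform(-2, 2), model.spheres[0], model)
            assert abs(ft) <= model.arrays.contact_mu * fn + 1e-12


class TestDynamics:
    def test_ballistic_com_acceleration(self, model):
        """Feet off the ground, muscles silent: COM falls at g."""
        q = np.zeros(9)
        q[1] = 2.0
        qd = np.zeros(9)
        dt = 1e-5
        ma = model.arrays
        coms = []
        for _ in range(3):
            coms.append(dyn.com_position(q, ma.parent, ma.jtype, ma.jsign,
                                         ma.jpos, ma.mass, ma.com))
            qdd = forward_dynamics(q, qd, np.zeros(9), model)
            qd = qd + qdd * dt
            q = q + qd * dt
        acc = (np.array(coms[2]) - 2 * np.array(coms[1]) + np.array(coms[0])) \
            / dt ** 2
        assert acc[0] == pytest.approx(0.0, abs=1e-4)
        assert acc[1] == pytest.approx(-9.81, abs=1e-3)

    def test_passive_pendulum_period(self, model):
        """One leg swinging about a pinned hip matches the compound-
        pendulum closed form within 1%."""
        segs = model.skeleton.segments
        mf, ms, mft = segs["femur"].mass, segs["shank"].mass, segs["foot"].mass
        I = segs["femur"].inertia + mf * 0.17 ** 2 \
            + segs["shank"].inertia + ms * 0.60 ** 2 \
            + segs["foot"].inertia + mft * (0.05 ** 2 + 0.89 ** 2)
        M = mf + ms + mft
        cx = mft * 0.05 / M
        cy = (mf * -0.17 + ms * -0.60 + mft * -0.89) / M
        Lc = np.hypot(cx, cy)
        T_closed = 2 * np.pi * np.sqrt(I / (M * 9.81 * Lc))

        locked = np.ones(9, dtype=bool)
        locked[3] = False
        eq = -np.arctan2(cx, -cy)
        q = np.zeros(9)
        q[1], q[3] = 3.0, eq + 0.02
        qd = np.zeros(9)
        dt = 1e-4
        crossings, prev = [], q[3] - eq
        for i in range(int(4.0 / dt)):
            qdd = forward_dynamics(q, qd, np.zeros(9), model, locked=locked)
            qd += qdd * dt
            q += qd * dt
            cur = q[3] - eq
            if prev < 0 <= cur:
                crossings.append(i * dt)
            prev = cur
        period = float(np.mean(np.diff(crossings)))
        assert period == pytest.approx(T_closed, rel=0.01)

    def test_energy_drift_below_tenth_percent_per_second(self, model, rng):
        """Passive contact-free motion conserves mechanical energy."""
        ma = model.arrays
        q = rng.normal(0, 0.3, 9)
        q[1] = 2.5
        qd = rng.normal(0, 0.5, 9)
        E0 = dyn.mechanical_energy(q, qd, ma.parent, ma.jtype, ma.jsign,
                                   ma.jpos, ma.mass, ma.com, ma.inertia,
                                   ma.anc, ma.gravity)
        dt = 1e-4
        for _ in range(10000):
            qdd = forward_dynamics(q, qd, np.zeros(9), model)
            qd += qdd * dt
            q += qd * dt
        E1 = dyn.mechanical_energy(q, qd, ma.parent, ma.jtype, ma.jsign,
                                   ma.jpos, ma.mass, ma.com, ma.inertia,
                                   ma.anc, ma.gravity)
        assert abs(E1 - E0) / abs(E0) < 1e-3

    def test_single_step_energy_change_tiny_at_rest(self, model):
        """No stimulation, no motion, no contact: one fine step moves
        mechanical energy by less than 1e-6 J."""
        st = model.initial_state()
        st.q[1] = 2.0           # airborne
        st.qd[:] = 0.0
        st.act[:] = 0.0
        ma = model.arrays
        E0 = dyn.mechanical_energy(st.q, st.qd, ma.parent, ma.jtype,
                                   ma.jsign, ma.jpos, ma.mass, ma.com,
                                   ma.inertia, ma.anc, ma.gravity)
        new = step_dynamics(st, np.zeros(18), 1e-5, model)
        E1 = dyn.mechanical_energy(new.q, new.qd, ma.parent, ma.jtype,
                                   ma.jsign, ma.jpos, ma.mass, ma.com,
                                   ma.inertia, ma.anc, ma.gravity)
        assert abs(E1 - E0) < 1e-6

    def test_step_dynamics_validates_dt_and_flags_blowup(self, model):
        st = model.initial_state()
        with pytest.raises(ValueError):
            step_dynamics(st, np.zeros(18), -1e-4, model)
        st.qd[0] = np.inf
        with pytest.raises(RuntimeError):
            step_dynamics(st, np.zeros(18), 1e-4, model)
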