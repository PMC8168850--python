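"""Reflex pathways, activation dynamics, delays, phases and parameters."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from reflexgait.reflex_controller import (DelayedSignalBuffer, GaitPhase,
                                          StateMachineThresholds,
                                          compose_stimulation,
                                          force_feedback, length_feedback,
                                          pd_balance, phase_transition,
                                          update_activation,
                                          velocity_feedback)


class TestPathwayLaws:
    def test_length_feedback(self):
        assert length_feedback(1.0, 0.5, 0.8) == 0.0
        assert length_feedback(2.0, 1.0, 0.8) == pytest.approx(0.4)
        assert length_feedback(0.0, 5.0, 0.8) == 0.0

    def test_velocity_feedback(self):
        assert velocity_feedback(1.0, -1.0) == 0.0
        assert velocity_feedback(0.5, 0.6) == pytest.approx(0.3)
        assert velocity_feedback(1.0, 0.0) == 0.0

    def test_force_feedback(self):
        assert force_feedback(1.2, 0.0) == 0.0
        assert force_feedback(1.2, 0.5) == pytest.approx(0.6)
        assert force_feedback(2.4, 0.5) == pytest.approx(2 * 0.6)

    def test_pd_balance(self):
        assert pd_balance(2.0, 0.5, 0.1, 0.0, 0.1) == 0.0
        assert pd_balance(2.0, 0.5, 0.2, 0.2, 0.1) == pytest.approx(0.3)
        assert pd_balance(0.0, 0.0, 1.0, 1.0, 0.0) == 0.0

    def test_contributions_nonnegative(self, rng):
        for _ in range(200):
            k = rng.uniform(0, 5)
            assert length_feedback(k, rng.normal(1, 0.5), rng.uniform(0.4, 1.4)) >= 0
            assert velocity_feedback(k, rng.normal(0, 2)) >= 0
            assert force_feedback(k, rng.uniform(0, 1)) >= 0


class TestActivationDynamics:
    def test_closed_form_value(self):
        a = update_activation(0.0, 1.0, 0.01, tau=0.01)
        assert a == pytest.approx(1 - np.exp(-1), abs=1e-15)

    def test_fixed_point_and_steady_state(self):
        assert update_activation(0.4, 0.4, 0.003) == pytest.approx(0.4, abs=1e-15)
        assert update_activation(0.0, 0.8, 10.0) == pytest.approx(0.8, abs=1e-12)

    def test_matches_numerical_integration(self, rng):
        """Exact discretization agrees with an ODE-solver oracle."""
        for _ in range(20):
            a0, u, dt = rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(1e-4, 0.05)
            sol = solve_ivp(lambda t, a: (u - a) / 0.01, (0, dt), [a0],
                            rtol=1e-12, atol=1e-14)
            assert update_activation(a0, u, dt) == pytest.approx(
                sol.y[0, -1], abs=1e-9)

    def test_converges_to_constant_drive_within_five_tau(self):
        a = 0.0
        for _ in range(50):                    # 5 tau at dt = tau/10
            a = update_activation(a, 0.05, 0.001, tau=0.01)
        assert a == pytest.approx(0.05, abs=0.05 * 0.01)


class TestDelayedSignals:
    def test_unit_step_delayed_exactly(self):
        dt = 1e-4
        buf = DelayedSignalBuffer(np.array(0.0), dt, max_delay=0.02)
        d_samples = 50                         # 5 ms
        out = []
        for k in range(300):
            buf.push(np.array(1.0 if k >= 100 else 0.0))
            out.append(float(buf.read_delayed(d_samples * dt)))
        # the delayed step rises exactly d_samples after the input step
        assert out[99 + d_samples] == 0.0
        assert out[100 + d_samples] == 1.0

    def test_before_history_returns_initial_sample(self):
        buf = DelayedSignalBuffer(np.array([3.0, 4.0]), 1e-3, max_delay=0.05)
        buf.push(np.array([9.0, 9.0]))
        assert np.all(buf.read_delayed(0.02) == [3.0, 4.0])

    def test_excessive_delay_rejected(self):
        buf = DelayedSignalBuffer(np.array(0.0), 1e-3, max_delay=0.02)
        buf.push(np.array(1.0))
        with pytest.raises(ValueError):
            buf.read_delayed(1.0)


class TestComposition:
    def _signals(self, f_sol=0.0):
        sig = {m: (1.0, 0.0, 0.0) for m in
               ("GMAX", "HAMS", "ILPSO", "RF", "VAS", "BFSH", "GAS", "SOL", "TA")}
        sig["SOL"] = (1.0, 0.0, f_sol)
        sig["trunk"] = (0.0, 0.0)
        return sig

    def test_feedforward_only(self, wiring):
        params, entries, _ = wiring
        p = params.replace_values(np.zeros(len(params)))
        p["KCGMAX_ST"] = 0.05
        u = compose_stimulation("GMAX", GaitPhase.ES, self._signals(), p, entries)
        assert u == pytest.approx(0.05)

    def test_upper_clamp(self, wiring):
        params, entries, _ = wiring
        p = params.replace_values(params.values)
        p["KFSOL_MS-PS"] = 10.0
        u = compose_stimulation("SOL", GaitPhase.MS, self._signals(f_sol=0.9),
                                p, entries)
        assert u == 1.0

    def test_soleus_force_feedback_composition(self, wiring):
        """SOL in MS: only the force pathway is wired -> u = kF * f."""
        params, entries, _ = wiring
        p = params.replace_values(np.zeros(len(params)))
        p["KFSOL_MS-PS"] = 1.2
        u = compose_stimulation("SOL", GaitPhase.MS, self._signals(f_sol=0.5),
                                p, entries)
        assert u == pytest.approx(1.2 * 0.5)

    def test_unwired_query_warns_and_returns_floor(self, wiring, caplog):
        params, entries, _ = wiring
        p = params.replace_values(np.zeros(len(params)))
        import logging
        with caplog.at_level(logging.WARNING):
            u = compose_stimulation("RF", GaitPhase.MS, self._signals(), p,
                                    entries)
        assert u == pytest.approx(0.01)
        assert any("no wired pathway" in r.message for r in caplog.records)


class TestPhaseMachine:
    thresholds = StateMachineThresholds(load_threshold=0.15, dist_es_ms=0.03,
                                        dist_s_lp=0.1)

    def _sensors(self, own=0.0, contra=0.0, contra_phase=GaitPhase.S,
                 pelvis=0.0, ankle=0.0):
        return {"own_load": own, "contra_load": contra,
                "contra_phase": contra_phase, "pelvis_x": pelvis,
                "ankle_x": ankle}

    def test_ms_to_ps_on_contralateral_landing(self):
        s = self._sensors(own=0.6, contra=0.4, contra_phase=GaitPhase.ES)
        assert phase_transition(GaitPhase.MS, s, self.thresholds) == GaitPhase.PS

    def test_ps_to_s_at_toe_off(self):
        s = self._sensors(own=0.05, contra=0.8)
        assert phase_transition(GaitPhase.PS, s, self.thresholds) == GaitPhase.S

    def test_lp_to_es_at_heel_strike(self):
        s = self._sensors(own=0.5)
        assert phase_transition(GaitPhase.LP, s, self.thresholds) == GaitPhase.ES

    def test_es_to_ms_when_pelvis_passes_ankle(self):
        s = self._sensors(own=0.6, pelvis=0.1, ankle=0.0)
        assert phase_transition(GaitPhase.ES, s, self.thresholds) == GaitPhase.MS

    def test_transitions_follow_legal_cycle_only(self, rng):
        legal = {GaitPhase.ES: {GaitPhase.ES, GaitPhase.MS},
                 GaitPhase.MS: {GaitPhase.MS, GaitPhase.PS},
                 GaitPhase.PS: {GaitPhase.PS, GaitPhase.S},
                 GaitPhase.S: {GaitPhase.S, GaitPhase.LP},
                 GaitPhase.LP: {GaitPhase.LP, GaitPhase.ES}}
        phase = GaitPhase.ES
        for _ in range(500):
            s = self._sensors(own=rng.uniform(0, 1), contra=rng.uniform(0, 1),
                              contra_phase=GaitPhase(int(rng.integers(0, 5))),
                              pelvis=rng.normal(0, 0.3),
                              ankle=rng.normal(0, 0.3))
            new = phase_transition(phase, s, self.thresholds)
            assert new in legal[phase]
            phase = new

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            StateMachineThresholds(load_threshold=1.5)


class TestParameterSet:
    def test_yaml_roundtrip_bit_exact(self, params, tmp_path, rng):
        p = params.replace_values(params.values + rng.normal(0, 0.1, len(params)))
        path = tmp_path / "values.yaml"
        p.to_yaml(path)
        q = params.replace_values(np.zeros(len(params)))
        q.load_values(path)
        assert np.array_equal(p.values, q.values)

    def test_bounds_and_categories(self, params):
        b = params.bounds()
        assert np.all(b[:, 0] <= b[:, 1])
        cats = set(params.categories())
        assert cats == {"reflex", "feedforward", "balance", "state"}

    def test_stretch_pairs_are_mutual(self, params):
        for name in params.reflex_names():
            partner = params.stretch_partner(name)
            if partner is not None:
                assert params.stretch_partner(partner) == name

    def test_delays_only_from_stated_set(self, wiring):
        _, _, cfg = wiring
        assert set(cfg["delays_ms"].values()) == {5, 10, 20}
        assert cfg["tau_activation"] == 0.01
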