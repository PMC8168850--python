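"""Solution selection, correlation screening, key identification,
regression and range comparison."""

import numpy as np
import pytest

from reflexgait.gait_objective import GaitMetrics
from reflexgait.solution_analysis import (SelectionRules, SolutionRecord,
                                          build_report, compare_ranges,
                                          correlations, cycle_convergence,
                                          fit_regression, identify_key,
                                          records_to_frame, frame_to_records,
                                          select, selected)
from reflexgait.synthetic_data import (PlantedEffect, PlantedEffectSpec,
                                       TraceSpec, synth_solutions,
                                       synth_trace)
from reflexgait.trace import CH_INDEX


def _record(params, speed=1.0, effort=3.0, hip=0.1, knee=0.1, ankle=0.5,
            sd=0.69, sl=0.72, set_id=1, fall=False, converged=True):
    m = GaitMetrics(speed=speed, step_length=sl, step_duration=sd,
                    effort=effort,
                    joint_penalties={"hip": hip, "knee": knee, "ankle": ankle},
                    head_penalty=0.1, time_sim=15.0, events=[], fall=fall,
                    usable=not fall)
    return SolutionRecord(values=params.values.copy(), metrics=m, cost=1.0,
                          set_id=set_id, target=speed, seed=0,
                          converged=converged)


class TestSelection:
    def test_effort_ceiling_mid_speed(self, params):
        r = _record(params, speed=1.0, effort=5.0)
        select([r])
        assert not r.selected and r.rejection == "effort"

    def test_relaxed_ceiling_for_slow_gaits(self, params):
        r = _record(params, speed=0.5, effort=7.0)
        select([r])
        assert r.selected

    def test_first_failed_rule_reported(self, params):
        r = _record(params, hip=0.6, ankle=2.9)
        select([r])
        assert not r.selected and r.rejection == "joints:hip"

    def test_set_windows(self, params):
        ok = _record(params, set_id=2, sd=0.695)
        bad = _record(params, set_id=2, sd=0.72)
        ok3 = _record(params, set_id=3, sl=0.73)
        bad3 = _record(params, set_id=3, sl=0.75)
        select([ok, bad, ok3, bad3])
        assert ok.selected and ok3.selected
        assert bad.rejection == "window:step_duration"
        assert bad3.rejection == "window:step_length"

    def test_fall_and_nonconvergence_rejected(self, params):
        r1 = _record(params, fall=True)
        r2 = _record(params, converged=False)
        select([r1, r2])
        assert r1.rejection == "stability:fall"
        assert r2.rejection == "stability:no-convergence"

    def test_idempotent_and_order_independent(self, params, rng):
        recs = [_record(params, speed=s, effort=e)
                for s, e in zip(rng.uniform(0.4, 1.8, 20),
                                rng.uniform(2, 9, 20))]
        select(recs)
        flags1 = [(r.selected, r.rejection) for r in recs]
        perm = list(rng.permutation(20))
        select([recs[i] for i in perm])
        select(recs)
        assert [(r.selected, r.rejection) for r in recs] == flags1

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            SelectionRules(effort_ceiling_mid=-1)
        with pytest.raises(ValueError):
            SelectionRules(sd_window=(0.5, 0.6))


class TestCycleConvergence:
    def test_periodic_trace_converges(self):
        assert cycle_convergence(synth_trace(TraceSpec(duration=10.0)))

    def test_drifting_trace_fails(self):
        tr = synth_trace(TraceSpec(duration=10.0))
        # inject a 5-degree-per-cycle ramp on one joint angle
        drift = np.radians(5.0) * tr.time / (2 * 0.7)
        tr.data[:, CH_INDEX["q_hip_r"]] += drift
        assert not cycle_convergence(tr, tol_deg=2.0)

    def test_too_few_cycles_fails(self):
        assert not cycle_convergence(synth_trace(TraceSpec(duration=3.0)))


class TestCorrelations:
    def test_parameter_equal_to_characteristic(self, params):
        recs = []
        rng = np.random.default_rng(0)
        i = params.index["KFSOL_MS-PS"]
        for _ in range(30):
            s = rng.uniform(0.5, 1.5)
            r = _record(params, speed=s)
            r.values[i] = s
            recs.append(r)
        table = correlations({1: recs}, params)
        assert table.loc["KFSOL_MS-PS", "speed"] == pytest.approx(1.0)

    def test_independent_parameter_small_correlation(self, params):
        spec = PlantedEffectSpec(n=150, seed=11, effects=[])
        table = correlations(synth_solutions(spec, params), params)
        for name in ("KFSOL_MS-PS", "KFGAS_MS-PS", "L0HAMS_LP",
                     "KLILPSO_PS", "L0TA_LP"):
            assert np.all(np.abs(table.loc[name].to_numpy(dtype=float)) < 0.2)

    def test_constant_parameter_degenerate(self, params):
        recs = [_record(params, speed=s) for s in np.linspace(0.5, 1.5, 10)]
        table = correlations({1: recs}, params)
        assert table.loc["KFSOL_MS-PS", "speed"] == 0.0
        assert table.attrs["degenerate"].loc["KFSOL_MS-PS", "speed"]

    def test_too_few_records_rejected(self, params):
        with pytest.raises(ValueError):
            correlations({1: [_record(params), _record(params)]}, params)


class TestIdentifyKey:
    def test_threshold_rule_and_partner_augmentation(self, params):
        spec = PlantedEffectSpec(n=100, seed=5, effects=[
            PlantedEffect("L0HAMS_LP", 2, 0.87),
        ])
        table = correlations(synth_solutions(spec, params), params)
        key = identify_key(table, params)
        assert "L0HAMS_LP" in key
        assert "KLHAMS_LP" in key          # stretch partner, below threshold

    def test_force_gain_has_no_partner(self, params):
        spec = PlantedEffectSpec(n=100, seed=6, effects=[
            PlantedEffect("KFSOL_MS-PS", 1, 0.9),
        ])
        table = correlations(synth_solutions(spec, params), params)
        assert identify_key(table, params) == ["KFSOL_MS-PS"]

    def test_all_noise_empty_key_set(self, params):
        spec = PlantedEffectSpec(n=150, seed=7, effects=[])
        table = correlations(synth_solutions(spec, params), params)
        assert identify_key(table, params) == []


class TestRegression:
    def test_exact_line(self):
        x = np.linspace(0, 1, 20)
        fit = fit_regression(x, 2 * x + 1)
        assert fit.order == 1 and fit.r2 == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx([2.0, 1.0], abs=1e-9)

    def test_noiseless_quadratic_needs_order_two(self):
        x = np.linspace(-1, 1, 30)
        y = x ** 2
        fit = fit_regression(x, y)
        assert fit.order == 2 and fit.r2 == pytest.approx(1.0)

    def test_pure_noise_flagged_at_max_order(self, rng):
        x = np.linspace(0, 1, 100)
        fit = fit_regression(x, rng.standard_normal(100))
        assert fit.order == 3 and fit.below_threshold

    def test_r2_nondecreasing_in_order(self, rng):
        x = rng.uniform(-1, 1, 50)
        y = np.sin(3 * x) + 0.2 * rng.standard_normal(50)
        r2 = []
        for order in (1, 2, 3):
            fit = fit_regression(x, y, r2_threshold=2.0, max_order=order)
            r2.append(fit.r2)
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 2e-12

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_regression(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            fit_regression(np.arange(3.0), np.arange(3.0))


class TestCompareRanges:
    def test_identical_datasets_full_coverage(self, params):
        recs = [_record(params, speed=s) for s in np.linspace(0.5, 1.5, 10)]
        df = compare_ranges({"full": recs, "key-only": recs})
        assert np.allclose(df["coverage"], 1.0)

    def test_constructed_extremes(self, params):
        full = [_record(params, speed=s) for s in (0.4, 1.8)]
        narrow = [_record(params, speed=s) for s in (0.8, 1.3)]
        df = compare_ranges({"full": full, "nonkey-only": narrow})
        row = df[(df.dataset == "nonkey-only")
                 & (df.characteristic == "speed")].iloc[0]
        assert row["min"] == 0.8 and row["max"] == 1.3
        assert row["coverage"] == pytest.approx(0.5 / 1.4)

    def test_empty_dataset_rejected(self, params):
        with pytest.raises(ValueError):
            compare_ranges({"full": []})


class TestReportAndFrames:
    def test_report_roundtrip_and_format(self, params, tmp_path):
        spec = PlantedEffectSpec.default(n=80, seed=3)
        recs = synth_solutions(spec, params)
        report = build_report(recs, params)
        text = report.to_json(tmp_path / "report.json")
        assert "key_parameters" in text
        assert "KFSOL_MS-PS" in report.formatted()
        for name in report.key_parameters:
            assert name in params.index

    def test_records_frame_roundtrip(self, params):
        recs = selected([_record(params, speed=s)
                         for s in np.linspace(0.5, 1.5, 8)])
        df = records_to_frame(recs, params)
        back = frame_to_records(df, params)
        assert len(back) == len(recs)
        assert np.allclose([r.metrics.speed for r in back],
                           [r.metrics.speed for r in recs])
        assert np.array_equal(back[0].values, recs[0].values)
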