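import numpy as np
import pytest

from whipneck.identify import (DesignVector, IdentificationSchedule,
                               IdentificationStep, IdentifySettings,
                               bottom_up_schedule, evaluate_objectives,
                               identify_step, load_schedule, rms_deviation,
                               save_schedule, sensitivity_analysis,
                               sequential_identify, table3_sequences,
                               table4_schedule)
from whipneck.synthref import generate_reference, lab_sled_motion

SETTINGS = IdentifySettings(rtol=1e-6, atol=1e-9, maxiter=15)


@pytest.fixture(scope="module")
def two_body_reference(two_body_model):
    motion = lab_sled_motion(0.1)
    return generate_reference(two_body_model, motion, t_end=0.1,
                              output_rate=2000, rtol=1e-6)


class TestRms:
    def test_sinusoid_against_zero(self):
        t = np.linspace(0, 2 * np.pi, 100001)
        assert rms_deviation(np.sin(t), np.zeros_like(t)) == pytest.approx(
            1.0 / np.sqrt(2.0), rel=1e-4)

    def test_identical_channels(self, rng):
        x = rng.normal(size=100)
        assert rms_deviation(x, x) == 0.0

    def test_resampling_path(self):
        t_ref = np.linspace(0, 1, 11)
        t_sim = np.linspace(0, 1, 101)
        v = rms_deviation(t_sim ** 2, t_ref ** 2, sim_time=t_sim,
                          ref_time=t_ref)
        assert v < 1e-12  # linear interp of exact samples

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            rms_deviation(np.zeros(5), np.zeros(7))


class TestDesignVector:
    def test_sizes(self, v1_model, v5b_model):
        assert len(DesignVector.from_model(v1_model)) == 40
        assert len(DesignVector.from_model(v5b_model)) == 42

    def test_bounds_bracket_negative_values(self, v1_model):
        dv = DesignVector.from_model(v1_model)
        lo, hi = dv.bounds_of("C7/T1.A1")
        v = v1_model.get_parameter("C7/T1.A1")
        assert v < 0
        assert lo == pytest.approx(1.25 * v)  # more negative
        assert hi == pytest.approx(0.75 * v)
        lo2, hi2 = dv.bounds_of("C7/T1.A2")
        v2 = v1_model.get_parameter("C7/T1.A2")
        assert (lo2, hi2) == (pytest.approx(0.75 * v2),
                              pytest.approx(1.25 * v2))

    def test_unknown_variable(self, v1_model):
        with pytest.raises(KeyError):
            DesignVector.from_model(v1_model).bounds_of("C9/T4.A1")


class TestSchedules:
    def test_bottom_up_covers_all_bodies(self, v5b_model):
        s = bottom_up_schedule(v5b_model)
        assert [st.objective for st in s.steps] == [
            "RMS_C7", "RMS_C6", "RMS_C5", "RMS_C4", "RMS_C3", "RMS_C2",
            "RMS_C1", "RMS_C0"]
        assert s.steps[-1].variables == (
            "C0/C1.A1", "C0/C1.B1", "C0/C1.A2", "C0/C1.B2", "C0/C1.C")

    def test_published_schedules_validate(self, v1_model, v5b_model):
        dv1 = DesignVector.from_model(v1_model)
        for s in table3_sequences():
            s.validate(dv1)
            assert len(s.steps) == 8
        dv2 = DesignVector.from_model(v5b_model)
        t4 = table4_schedule()
        t4.validate(dv2)
        assert [st.objective for st in t4.steps] == [
            "RMS_OC", "RMS_OC", "RMS_OC", "RMS_C0"]
        assert t4.steps[2].variables == ("kv",)

    def test_validate_rejects_unknown_variable(self, v1_model):
        s = IdentificationSchedule(
            (IdentificationStep("RMS_C7", ("C7/T1.A9",)),))
        with pytest.raises(ValueError, match="unknown design"):
            s.validate(DesignVector.from_model(v1_model))

    def test_yaml_round_trip(self, tmp_path):
        s = table4_schedule()
        p = tmp_path / "schedule.yaml"
        save_schedule(s, p)
        s2 = load_schedule(p)
        assert s2.steps == s.steps
        assert s2.name == s.name


class TestObjectives:
    def test_truth_scores_near_zero(self, two_body_model, two_body_reference):
        obj = evaluate_objectives(two_body_model, two_body_reference,
                                  SETTINGS)
        assert set(obj) == {"RMS_C7", "RMS_C6"}
        assert all(v < 1e-6 for v in obj.values())

    def test_oc_objective_present_with_slider(self, v5b_model):
        motion = lab_sled_motion(0.05)
        ref = generate_reference(v5b_model, motion, t_end=0.05,
                                 output_rate=2000, rtol=1e-6)
        obj = evaluate_objectives(v5b_model, ref, SETTINGS)
        assert "RMS_OC" in obj


class TestIdentifyStep:
    def test_never_worse_than_start(self, two_body_model,
                                    two_body_reference):
        pert = two_body_model.with_parameter("C7/T1.A1", -0.37)
        fitted, hist = identify_step(
            pert, two_body_reference, "RMS_C7",
            ["C7/T1.A1", "C7/T1.B1"], settings=SETTINGS)
        assert hist["rms_final"] <= hist["rms_initial"]
        assert hist["rms_final"] < 0.5 * hist["rms_initial"]

    def test_bounds_respected(self, two_body_model, two_body_reference):
        pert = two_body_model.with_parameter("C7/T1.A1", -0.37)
        dv = DesignVector.from_model(pert)
        fitted, _ = identify_step(pert, two_body_reference, "RMS_C7",
                                  ["C7/T1.A1", "C7/T1.C"],
                                  settings=SETTINGS)
        for name in ("C7/T1.A1", "C7/T1.C"):
            lo, hi = dv.bounds_of(name)
            assert lo - 1e-12 <= fitted.get_parameter(name) <= hi + 1e-12

    def test_fixed_point_at_truth(self, two_body_model, two_body_reference):
        fitted, hist = identify_step(
            two_body_model, two_body_reference, "RMS_C6",
            ["C6/C7.A1", "C6/C7.B1"], settings=SETTINGS)
        assert hist["rms_final"] <= hist["rms_initial"]
        assert hist["rms_final"] < 1e-6

    def test_zero_start_value_rejected(self, two_body_model,
                                       two_body_reference):
        m = two_body_model.with_parameter("C6/C7.C", 0.0)
        with pytest.raises(ValueError, match="zero-valued"):
            identify_step(m, two_body_reference, "RMS_C6", ["C6/C7.C"],
                          settings=SETTINGS)


class TestSequential:
    def test_loop_contract_and_improvement(self, two_body_model,
                                           two_body_reference):
        rng = np.random.default_rng(3)
        start = two_body_model
        dv = DesignVector.from_model(two_body_model)
        for var in dv.names():
            v = two_body_model.get_parameter(var)
            start = start.with_parameter(
                var, v * (1.0 + rng.uniform(-0.15, 0.15)))
        sched = bottom_up_schedule(start)
        fitted, trace = sequential_identify(
            start, two_body_reference, sched, max_sequences=2,
            settings=SETTINGS)
        assert trace[0]["sequence"] == 0
        assert 2 <= len(trace) <= 3
        for key in ("RMS_C7", "RMS_C6"):
            assert trace[-1][key] <= trace[0][key]
        # fitted parameters stay inside the +/-25% box of the start
        dv_start = DesignVector.from_model(start)
        for var in dv_start.names():
            lo, hi = dv_start.bounds_of(var)
            assert lo - 1e-12 <= fitted.get_parameter(var) <= hi + 1e-12


class TestSensitivity:
    def test_influence_table(self, two_body_model, two_body_reference):
        table = sensitivity_analysis(two_body_model, two_body_reference,
                                     settings=SETTINGS,
                                     variables=["C7/T1.A1", "C6/C7.A1",
                                                "C6/C7.C"])
        assert list(table.columns) == ["RMS_C7", "RMS_C6"]
        assert table.shape == (3, 2)
        # perturbing the lower joint must disturb the lower body's RMS
        assert abs(table.loc["C7/T1.A1", "RMS_C7"]) > 0
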