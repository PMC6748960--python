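"""Protocol layer: metrics, task construction, trial loop contracts."""

import numpy as np
import pytest

from cbgreach.config import RunConfig
from cbgreach.motor_cortex import LesionSpec
from cbgreach.protocols import (TaskSpec, compute_prv, compute_reaching_error,
                                make_task, run_trial, target_layout)


class TestMetrics:
    def test_constant_position_has_zero_prv_and_fixed_error(self):
        pos = np.tile([0.1, 0.2], (20, 1))
        speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) / 0.1
        assert compute_prv(speed) == 0.0
        assert compute_reaching_error(pos, [0.4, 0.6]) == pytest.approx(0.5)

    def test_trace_through_target_has_zero_error(self):
        pos = np.stack([np.linspace(0, 1, 11), np.zeros(11)], axis=1)
        assert compute_reaching_error(pos, [0.5, 0.0]) == pytest.approx(0.0)

    def test_triangular_profile_peak_recovered(self):
        speed = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        # window-1 smoothing: the apex itself
        assert compute_prv(speed, window=1) == pytest.approx(1.0)
        # moving average lowers but keeps an interior peak
        assert 0.8 < compute_prv(speed, window=5) <= 1.0

    def test_empty_trace(self):
        assert compute_prv([]) == 0.0


class TestTasks:
    def test_near_target_at_half_the_far_distance(self, trained_model):
        lay = target_layout(trained_model.right)
        x0 = lay["rest"]
        d_far = np.linalg.norm(lay["far"] - x0)
        d_near = np.linalg.norm(lay["near"] - x0)
        assert d_far == pytest.approx(0.3, abs=0.02)
        assert d_near == pytest.approx(0.5 * d_far, abs=0.03)

    def test_congruent_gives_paretic_the_near_target(self, trained_model):
        t = make_task(trained_model, "congruent", "bimanual")
        d_r = np.linalg.norm(t.targets["right"] - trained_model.right.rest_position())
        d_l = np.linalg.norm(t.targets["left"] - trained_model.left.rest_position())
        assert d_r == pytest.approx(0.5 * d_l, abs=0.03)

    def test_incongruent_reverses_the_assignment(self, trained_model):
        t = make_task(trained_model, "incongruent", "bimanual")
        d_r = np.linalg.norm(t.targets["right"] - trained_model.right.rest_position())
        d_l = np.linalg.norm(t.targets["left"] - trained_model.left.rest_position())
        assert d_l == pytest.approx(0.5 * d_r, abs=0.03)

    @pytest.mark.parametrize("name,eps", [
        ("symmetric", (-0.5, 0.5)),
        ("congruent", (-0.2, 0.89)),
        ("incongruent", (-0.2, 0.8)),
    ])
    def test_bimanual_coupling_presets(self, trained_model, name, eps):
        t = make_task(trained_model, name, "bimanual")
        assert (t.eps_right, t.eps_left) == eps

    def test_unimanual_coupling_is_zero(self, trained_model):
        t = make_task(trained_model, "symmetric", "unimanual")
        assert t.eps_right == 0.0 and t.eps_left == 0.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec(name="x", condition="trimanual", targets={"right": [0, 0]})

    def test_moving_arm_needs_a_target(self):
        with pytest.raises(ValueError):
            TaskSpec(name="x", condition="unimanual", targets={}, arms=("right",))


class TestTrialLoop:
    def test_zero_step_trial_reports_initial_distance(self, trained_model, rng):
        task = make_task(trained_model, "symmetric", "unimanual", moving=("right",))
        rec = run_trial(trained_model, task, rng, steps=0)
        d0 = np.linalg.norm(trained_model.right.rest_position()
                            - task.targets["right"])
        assert rec.error["right"] == pytest.approx(d0)
        assert rec.prv["right"] == 0.0

    def test_same_seed_reproduces_trial_exactly(self, trained_model):
        task = make_task(trained_model, "symmetric", "bimanual")
        r1 = run_trial(trained_model, task, np.random.default_rng(5))
        r2 = run_trial(trained_model, task, np.random.default_rng(5))
        assert np.array_equal(r1.positions["right"], r2.positions["right"])
        assert np.array_equal(r1.positions["left"], r2.positions["left"])

    def test_record_metrics_consistent_with_traces(self, trained_model, rng):
        task = make_task(trained_model, "symmetric", "unimanual", moving=("right",))
        rec = run_trial(trained_model, task, rng)
        pos = rec.positions["right"]
        cfg = trained_model.config
        speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) / cfg.cann.dt
        assert rec.prv["right"] == pytest.approx(
            compute_prv(speeds, window=cfg.task.smooth_window))
        assert rec.error["right"] == pytest.approx(
            compute_reaching_error(pos, task.targets["right"]))
        assert rec.success["right"] == (rec.error["right"]
                                        <= cfg.task.reach_threshold)

    def test_cimt_moves_only_the_paretic_arm(self, trained_model, rng):
        task = make_task(trained_model, "symmetric", "cimt")
        rec = run_trial(trained_model, task, rng, steps=20)
        assert set(rec.positions) == {"right"}

    def test_trained_reach_succeeds_with_unimodal_profile(self, trained_model):
        # single burst of movement: smoothed speed has one dominant peak and
        # decays after it (the rising phase is compressed into the first few
        # integration steps because the arm is kinematic, without inertia)
        task = make_task(trained_model, "symmetric", "unimanual", moving=("right",))
        rec = run_trial(trained_model, task, np.random.default_rng(9))
        assert rec.error["right"] < 0.05
        v = np.convolve(rec.speeds["right"], np.ones(5) / 5, mode="valid")
        peak = int(np.argmax(v))
        after = v[peak:]
        assert after[-1] < 0.1 * v[peak]  # movement terminates
        # no comparable secondary burst away from the main peak
        away = np.concatenate([v[:max(peak - 5, 0)], v[peak + 5:]])
        assert away.max() < 0.5 * v[peak]

    def test_bg_diagnostics_recorded_during_exploration(self, trained_model, rng):
        task = make_task(trained_model, "symmetric", "unimanual", moving=("right",))
        rec = run_trial(trained_model, task, rng, A_BG=1.0, A_PFC=0.0, steps=30)
        trace = rec.bg_trace["right"]
        assert len(trace) == 30
        assert all(0 < t["V"] <= 1 for t in trace)
        assert all(0 < t["gate_D1"] < 1 and 0 < t["gate_D2"] < 1 for t in trace)
        assert any(t["y_STN_std"] > 0.05 for t in trace)  # lattice oscillates

    def test_acute_lesion_lowers_paretic_prv(self, trained_model):
        task = make_task(trained_model, "symmetric", "unimanual", moving=("right",))
        lesion = LesionSpec(size=5, centre=trained_model.right.goal_node(
            task.targets["right"]))
        prv_i, prv_l = [], []
        for k in range(3):
            prv_i.append(run_trial(trained_model, task,
                                   np.random.default_rng(40 + k)).prv["right"])
            prv_l.append(run_trial(trained_model, task, np.random.default_rng(40 + k),
                                   lesions={"right": lesion}).prv["right"])
        assert np.mean(prv_l) < np.mean(prv_i)
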