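"""Resource-limited update rule and the goal-density constructors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repi import (
    DiscreteDensity,
    LatentConfig,
    TaskMapping,
    UpdateParams,
    bias_goal,
    default_mappings,
    make_density,
    observation_goal,
    response_goal,
    response_side_goal,
    soft_one_hot,
    step_update,
    task_goal,
    total_variation,
    uniform_density,
)
from repi.paradigms import OBJECT_LABELS, SIDES

PARAMS = UpdateParams()  # alpha 0.01, epsilon 6, dt 10 -> c = 0.06
TASKS = ("form", "color", "latent")


class TestStepUpdate:
    def test_moves_toward_goal_by_exact_affine_form(self):
        prior = uniform_density(SIDES)
        goal = DiscreteDensity(SIDES, [1.0, 0.0])
        out = step_update(prior, goal, PARAMS)
        np.testing.assert_allclose(out.weights, [0.56 / 1.06, 0.5 / 1.06], atol=1e-15)

    def test_goal_is_fixed_point(self):
        d = make_density(SIDES, [0.3, 0.7])
        out = step_update(d, d, PARAMS)
        np.testing.assert_allclose(out.weights, d.weights, atol=1e-15)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        pw=st.lists(st.floats(1e-4, 1.0), min_size=3, max_size=3),
        gw=st.lists(st.floats(1e-4, 1.0), min_size=3, max_size=3),
    )
    def test_exact_tv_contraction(self, pw, gw):
        """One step shrinks the total-variation distance to the goal by
        exactly 1/(1+c)."""
        labels = ("x", "y", "z")
        prior, goal = make_density(labels, pw), make_density(labels, gw)
        out = step_update(prior, goal, PARAMS)
        want = total_variation(prior, goal) / (1.0 + PARAMS.c)
        assert total_variation(out, goal) == pytest.approx(want, abs=1e-12)

    def test_uniform_reaches_09_at_iteration_28(self):
        """Scalar recurrence oracle: leading weight 1 - 0.5 (1+c)^-t first
        reaches 0.9 at t = 28 for c = 0.06."""
        oracle_first = next(
            t for t in range(1, 100) if 1 - 0.5 * (1 + PARAMS.c) ** (-t) >= 0.9
        )
        assert oracle_first == 28
        d = uniform_density(SIDES)
        goal = DiscreteDensity(SIDES, [1.0, 0.0])
        ticks = 0
        while d.weights[0] < 0.9:
            d = step_update(d, goal, PARAMS)
            ticks += 1
        assert ticks == oracle_first

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            step_update(uniform_density(SIDES), uniform_density(("a", "b")), PARAMS)


class TestTaskGoal:
    def test_prepared_two_tasks(self):
        g = task_goal(TASKS, None, ("form", "color"), 0.2, 0.9)
        np.testing.assert_allclose(g.weights, [0.4, 0.4, 0.2])

    def test_cued(self):
        g = task_goal(TASKS, "form", ("form", "color"), 0.1, 0.9)
        np.testing.assert_allclose(g.weights, [0.9, 0.0, 0.1])

    def test_fully_habitual(self):
        g = task_goal(TASKS, None, (), 1.0, 0.9)
        np.testing.assert_allclose(g.weights, [0.0, 0.0, 1.0])

    def test_dormant_slots_get_zero_mass(self):
        labels = ("form", "color", "dormant_0", "latent")
        g = task_goal(labels, None, ("form", "color"), 0.2, 0.9)
        np.testing.assert_allclose(g.weights, [0.4, 0.4, 0.0, 0.2])

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            task_goal(TASKS, "shape", ("form",), 0.1, 0.9)
        with pytest.raises(ValueError):
            task_goal(TASKS, None, ("shape",), 0.1, 0.9)


class TestObservationAndBiasGoals:
    def test_visible_stimulus_soft_one_hot(self):
        g = observation_goal(True, "black_star", OBJECT_LABELS, None, 0.97)
        assert g["black_star"] == pytest.approx(0.97)
        assert g["white_circle"] == pytest.approx(0.01)

    def test_topdown_expectation_uniform(self):
        task = make_density(TASKS, [0.8, 0.0, 0.2])
        g = observation_goal(False, None, OBJECT_LABELS, task, 0.97)
        np.testing.assert_allclose(g.weights, 0.25)

    def test_missing_object_while_visible(self):
        with pytest.raises(ValueError):
            observation_goal(True, None, OBJECT_LABELS, None, 0.97)

    def test_central_stimulus_copies_feedback(self):
        for w in ([0.5, 0.5], [0.7, 0.3]):
            s = make_density(SIDES, w)
            assert bias_goal(None, SIDES, s, 0.97) == s

    def test_lateral_pure_evidence(self):
        g = bias_goal("left", SIDES, uniform_density(SIDES), 0.97, 1.0)
        np.testing.assert_allclose(g.weights, [0.97, 0.03])

    def test_lateral_mixes_evidence_with_feedback(self):
        s = make_density(SIDES, [0.8, 0.2])
        g = bias_goal("left", SIDES, s, 0.97, 0.5)
        np.testing.assert_allclose(g.weights, [0.5 * 0.97 + 0.5 * 0.8, 0.5 * 0.03 + 0.5 * 0.2])

    def test_unknown_side(self):
        with pytest.raises(ValueError):
            bias_goal("up", SIDES, uniform_density(SIDES), 0.97)


class TestResponseSideGoal:
    def setup_method(self):
        self.mappings = default_mappings()

    def test_pure_form_task_maps_star_left(self):
        task = DiscreteDensity(TASKS, [1.0, 0.0, 0.0])
        obs = soft_one_hot(OBJECT_LABELS, "black_star", 1.0)
        g = response_side_goal(obs, task, uniform_density(SIDES), self.mappings)
        np.testing.assert_allclose(g.weights, [1.0, 0.0])

    def test_pure_latent_passes_bias_through(self):
        task = DiscreteDensity(TASKS, [0.0, 0.0, 1.0])
        bias = make_density(SIDES, [0.97, 0.03])
        g = response_side_goal(
            uniform_density(OBJECT_LABELS), task, bias, self.mappings
        )
        np.testing.assert_allclose(g.weights, bias.weights)

    def test_incompatible_bias_dilutes_mapping(self):
        task = DiscreteDensity(TASKS, [0.9, 0.0, 0.1])
        obs = soft_one_hot(OBJECT_LABELS, "black_star", 1.0)
        bias = make_density(SIDES, [0.03, 0.97])
        g = response_side_goal(obs, task, bias, self.mappings)
        np.testing.assert_allclose(g.weights, [0.903, 0.097], atol=1e-12)

    def test_linear_in_bias(self):
        task = DiscreteDensity(TASKS, [0.5, 0.2, 0.3])
        obs = soft_one_hot(OBJECT_LABELS, "white_circle", 0.8)
        b1, b2 = make_density(SIDES, [0.9, 0.1]), make_density(SIDES, [0.2, 0.8])
        mix = DiscreteDensity(SIDES, 0.5 * b1.weights + 0.5 * b2.weights)
        g_mix = response_side_goal(obs, task, mix, self.mappings)
        g1 = response_side_goal(obs, task, b1, self.mappings)
        g2 = response_side_goal(obs, task, b2, self.mappings)
        np.testing.assert_allclose(
            g_mix.weights, 0.5 * g1.weights + 0.5 * g2.weights, atol=1e-12
        )

    def test_mirror_invariance(self):
        """Swapping left/right in mappings and bias mirrors the goal."""
        task = DiscreteDensity(TASKS, [0.6, 0.3, 0.1])
        obs = soft_one_hot(OBJECT_LABELS, "black_circle", 0.9)
        bias = make_density(SIDES, [0.7, 0.3])
        mirrored = tuple(
            TaskMapping(m.task_label, m.side_labels, m.object_labels, m.matrix[::-1])
            for m in self.mappings
        )
        g = response_side_goal(obs, task, bias, self.mappings)
        gm = response_side_goal(
            obs, task, make_density(SIDES, bias.weights[::-1]), mirrored
        )
        np.testing.assert_array_equal(gm.weights, g.weights[::-1])


class TestResponseGoal:
    def test_uniform_before_onset(self):
        s = make_density(SIDES, [0.8, 0.2])
        np.testing.assert_allclose(response_goal(False, s, SIDES).weights, 0.5)

    def test_copies_side_after_onset(self):
        s = make_density(SIDES, [0.8, 0.2])
        assert response_goal(True, s, SIDES) == s


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tw=st.lists(st.floats(0.001, 1.0), min_size=3, max_size=3),
    ow=st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
    bw=st.lists(st.floats(0.001, 1.0), min_size=2, max_size=2),
)
def test_goal_constructors_return_valid_densities(tw, ow, bw):
    task = make_density(TASKS, tw)
    obs = make_density(OBJECT_LABELS, ow)
    bias = make_density(SIDES, bw)
    for g in (
        response_side_goal(obs, task, bias, default_mappings()),
        bias_goal("left", SIDES, bias, 0.97, 0.5),
        bias_goal(None, SIDES, bias, 0.97),
        observation_goal(False, None, OBJECT_LABELS, task, 0.97),
        task_goal(TASKS, None, ("form",), 0.15, 0.9),
    ):
        assert np.all(g.weights >= 0)
        assert np.sum(g.weights) == pytest.approx(1.0, abs=1e-9)
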