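"""The five-channel architecture advanced in discrete time through trials.

Five density channels — observation (O), stimulus-side bias (B), task
set (Psi), response side (S), overt response (R) — are wired together:
task-specific mapping matrices push the observation density onto
response sides weighted by task activity, the latent habitual channel
adds the stimulus-side bias, and the overt response density chases the
response-side density once the imperative stimulus appears.  Every
channel is pulled toward its goal with the same resource-limited update
each 10 ms tick; a response fires when the overt response density
crosses a threshold, after which the response-related densities reset to
uniform while perceptual and task densities carry their residual
activity into the next trial — the mechanism behind the sequential
effects the simulator reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .densities import DiscreteDensity, kl_array, uniform_density
from .effort import step_evidence_cost
from .dynamics import (
    LATENT_TASK,
    LatentConfig,
    TaskMapping,
    UpdateParams,
    bias_goal,
    observation_goal,
    response_goal,
    response_side_goal,
    step_update,
    task_goal,
)
from .paradigms import OBJECT_LABELS, SIDES, Trial, phase_at

__all__ = [
    "ModelConfig",
    "ModelState",
    "TraceRecord",
    "TrialResult",
    "default_mappings",
    "init_state",
    "advance",
    "check_response",
    "post_response_reset",
    "run_trial",
    "trace_to_frame",
]

CHANNELS = ("obs", "bias", "task", "side", "response")


def default_mappings(
    side_labels: Sequence[str] = SIDES,
    object_labels: Sequence[str] = OBJECT_LABELS,
) -> Tuple[TaskMapping, TaskMapping]:
    """The form and color task mappings over the crossed stimulus set.

    Form task: star -> left, circle -> right (either color).
    Color task: black -> left, white -> right (either form).
    """
    side_labels = tuple(side_labels)
    object_labels = tuple(object_labels)
    left = side_labels[0]

    def matrix(predicate) -> np.ndarray:
        m = np.zeros((len(side_labels), len(object_labels)))
        for j, lab in enumerate(object_labels):
            color, form = lab.split("_")
            i = 0 if predicate(form, color) else 1
            m[i, j] = 1.0
        return m

    form = TaskMapping(
        "form", side_labels, object_labels, matrix(lambda f, c: f == "star")
    )
    color = TaskMapping(
        "color", side_labels, object_labels, matrix(lambda f, c: c == "black")
    )
    return form, color


@dataclass(frozen=True)
class ModelConfig:
    """Full model configuration: label spaces, mappings and parameters.

    ``response_threshold`` is the overt-response weight that triggers a
    response (must exceed 0.5 so the trigger is unambiguous);
    ``timeout_ms`` bounds the post-stimulus wait before an omission is
    recorded; ``motor_delay_ms`` is an optional additive offset on
    reported reaction times (default 0).  ``instant_perception`` clamps
    the observation channel to its goal each tick instead of letting it
    adapt, removing the perceptual dynamics from the loop.
    """

    params: UpdateParams = UpdateParams()
    latent: LatentConfig = LatentConfig()
    mappings: Tuple[TaskMapping, ...] = field(default_factory=default_mappings)
    prepared_tasks: Tuple[str, ...] = ("form", "color")
    n_dormant_tasks: int = 0
    response_threshold: float = 0.9
    timeout_ms: float = 5000.0
    motor_delay_ms: float = 0.0
    instant_perception: bool = False
    focus_task_when_solving: bool = False
    bias_feedback_source: str = "side"
    object_labels: Tuple[str, ...] = OBJECT_LABELS
    side_labels: Tuple[str, ...] = SIDES

    def __post_init__(self):
        if not (0.5 < self.response_threshold <= 1.0):
            raise ValueError("response_threshold must lie in (0.5, 1]")
        if self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be positive")
        if self.bias_feedback_source not in ("side", "response"):
            raise ValueError("bias_feedback_source must be 'side' or 'response'")
        mapped = {m.task_label for m in self.mappings}
        if not set(self.prepared_tasks) <= mapped:
            raise ValueError("every prepared task needs a mapping")
        for m in self.mappings:
            if m.object_labels != tuple(self.object_labels):
                raise ValueError("mapping object labels inconsistent with config")
            if m.side_labels != tuple(self.side_labels):
                raise ValueError("mapping side labels inconsistent with config")

    @property
    def task_labels(self) -> Tuple[str, ...]:
        """Mapped tasks, then dormant slots, then the latent channel last."""
        dormant = tuple(f"dormant_{i}" for i in range(self.n_dormant_tasks))
        return tuple(m.task_label for m in self.mappings) + dormant + (LATENT_TASK,)

    @classmethod
    def for_paradigm(cls, paradigm: str, **overrides) -> "ModelConfig":
        """Default configuration for ``"simon"`` or ``"switching"``."""
        if paradigm == "simon":
            overrides.setdefault("prepared_tasks", ("form",))
        elif paradigm == "switching":
            overrides.setdefault("prepared_tasks", ("form", "color"))
        else:
            raise ValueError(f"unknown paradigm {paradigm!r}")
        return cls(**overrides)

    def with_latent_level(self, level: float) -> "ModelConfig":
        """Config with the habitual channel pinned at ``level`` throughout.

        Sets both latent activity values to ``level`` and the cue goal to
        ``1 - level`` on the cued task, so ``level = 0`` removes the
        latent stimulus-side -> response-side channel entirely.
        """
        latent = replace(
            self.latent,
            lambda_iti=level,
            lambda_active=level,
            cue_strength=1.0 - level,
        )
        return replace(self, latent=latent)


@dataclass(frozen=True)
class ModelState:
    """All five channel densities plus the simulation clock and phase."""

    obs: DiscreteDensity
    bias: DiscreteDensity
    task: DiscreteDensity
    side: DiscreteDensity
    response: DiscreteDensity
    tick_index: int = 0
    t_in_trial_ms: float = 0.0
    phase: str = "iti"


@dataclass(frozen=True)
class TraceRecord:
    """One tick of the simulation: post-update densities, the goals that
    drove the update, and the response-side refocusing cost of the step."""

    t_ms: float  # ms from trial start, after this step
    phase: str  # phase during which this step was computed
    densities: dict  # channel -> DiscreteDensity (post-update)
    goals: dict  # channel -> DiscreteDensity
    step_cost: float  # evidence-weighted response-side cost, nats
    goal_cost: float  # KL(G(S) || P(S)) for this step, nats


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial.

    ``response`` is None and ``timeout`` True for omissions; ``rt_ms``
    is the time from stimulus onset to threshold crossing (plus any
    configured motor delay).  ``integrated_cost`` sums the per-tick
    response-side refocusing cost from stimulus onset through the
    response (or timeout) tick, in nats.
    """

    trial_index: int
    response: Optional[str]
    rt_ms: Optional[float]
    correct: Optional[bool]
    integrated_cost: float
    timeout: bool


def init_state(config: ModelConfig) -> ModelState:
    """Resting state before an experiment: uniform response-related
    densities, top-down (uniform) observation expectation, and the
    inter-trial task readiness over the prepared tasks."""
    task = task_goal(
        config.task_labels,
        cued=None,
        prepared_set=config.prepared_tasks,
        latent_level=config.latent.lambda_iti,
        cue_strength=config.latent.cue_strength,
    )
    return ModelState(
        obs=uniform_density(config.object_labels),
        bias=uniform_density(config.side_labels),
        task=task,
        side=uniform_density(config.side_labels),
        response=uniform_density(config.side_labels),
    )


def _goals(state: ModelState, trial: Trial, config: ModelConfig, phase: str) -> dict:
    """All five goal densities, computed from the pre-update state."""
    visible = phase == "stimulus"
    cue_on = phase in ("fixation_or_cue", "stimulus")
    lat = config.latent
    # While actually solving the trial the task goal strives for full
    # focus on the cued task; during preparation the cue goal retains
    # the latent readiness mass.
    cue_strength = (
        1.0 if (visible and config.focus_task_when_solving) else lat.cue_strength
    )
    g_task = task_goal(
        config.task_labels,
        cued=trial.cued_task if cue_on else None,
        prepared_set=config.prepared_tasks,
        latent_level=lat.lambda_iti if phase == "iti" else lat.lambda_active,
        cue_strength=cue_strength,
    )
    g_obs = observation_goal(
        visible,
        trial.obj.label if visible else None,
        config.object_labels,
        state.task,
        lat.stimulus_mass,
    )
    feedback = state.side if config.bias_feedback_source == "side" else state.response
    g_bias = bias_goal(
        trial.lateral_side if visible else None,
        config.side_labels,
        feedback,
        lat.side_mass,
        lat.bias_evidence_weight,
    )
    g_side = response_side_goal(state.obs, state.task, state.bias, config.mappings)
    g_resp = response_goal(visible, state.side, config.side_labels)
    return {
        "obs": g_obs,
        "bias": g_bias,
        "task": g_task,
        "side": g_side,
        "response": g_resp,
    }


def advance(
    state: ModelState, trial: Trial, config: ModelConfig
) -> Tuple[ModelState, TraceRecord]:
    """One synchronous tick: compute every goal from the pre-update
    state, then pull every channel toward its goal simultaneously.

    In instant-perception mode the observation channel is set directly
    to its goal rather than adapted.  The returned record carries the
    post-update densities and two response-side cost measures computed
    from the pre-update state: the evidence-weighted cost (headline)
    and the goal divergence KL(G(S) || P(S)).
    """
    phase = phase_at(trial, state.t_in_trial_ms)
    goals = _goals(state, trial, config, phase)
    p = config.params
    step_cost = step_evidence_cost(
        state.obs, state.task, state.bias, state.side, config.mappings
    )
    goal_cost = kl_array(goals["side"].weights, state.side.weights)
    new = ModelState(
        obs=goals["obs"] if config.instant_perception
        else step_update(state.obs, goals["obs"], p),
        bias=step_update(state.bias, goals["bias"], p),
        task=step_update(state.task, goals["task"], p),
        side=step_update(state.side, goals["side"], p),
        response=step_update(state.response, goals["response"], p),
        tick_index=state.tick_index + 1,
        t_in_trial_ms=state.t_in_trial_ms + p.dt_ms,
        phase=phase,
    )
    record = TraceRecord(
        t_ms=new.t_in_trial_ms,
        phase=phase,
        densities={
            "obs": new.obs,
            "bias": new.bias,
            "task": new.task,
            "side": new.side,
            "response": new.response,
        },
        goals=goals,
        step_cost=step_cost,
        goal_cost=goal_cost,
    )
    return new, record


def check_response(
    response_density: DiscreteDensity, threshold: float
) -> Optional[str]:
    """The response label whose weight reached ``threshold`` (inclusive),
    or None if no weight has; ties break by label order (cannot occur
    for thresholds above 0.5)."""
    i = int(np.argmax(response_density.weights))
    if response_density.weights[i] >= threshold:
        return response_density.labels[i]
    return None


def post_response_reset(state: ModelState, config: ModelConfig) -> ModelState:
    """After a response, response-side and overt-response densities snap
    back to uniform; observation, bias and task densities carry over
    (their residual activity drives switch and repetition effects)."""
    return replace(
        state,
        side=uniform_density(config.side_labels),
        response=uniform_density(config.side_labels),
        phase="post_response",
    )


def run_trial(
    state: ModelState,
    trial: Trial,
    config: ModelConfig,
    record_trace: bool = False,
) -> Tuple[ModelState, TrialResult, List[TraceRecord]]:
    """Advance tick-by-tick through one trial until response or timeout.

    The trial runs ITI -> fixation/cue -> stimulus; from stimulus onset
    the overt response density accumulates toward the response-side
    density and the trial ends when it crosses the threshold (reaction
    time = crossing time - stimulus onset) or when ``timeout_ms`` passes
    without a crossing (omission).  Response-related densities are reset
    afterwards and the carried-over state is returned.
    """
    state = replace(state, t_in_trial_ms=0.0, phase="iti")
    onset = trial.schedule.stimulus_onset_ms
    trace: List[TraceRecord] = []
    cost = 0.0
    correct_side = None
    for m in config.mappings:
        if m.task_label == trial.cued_task:
            correct_side = m.map_object(trial.obj.label)
    if correct_side is None:
        raise ValueError(f"no mapping for cued task {trial.cued_task!r}")

    while True:
        in_window = phase_at(trial, state.t_in_trial_ms) == "stimulus"
        state, rec = advance(state, trial, config)
        if record_trace:
            trace.append(rec)
        if in_window:
            cost += rec.step_cost
            resp = check_response(state.response, config.response_threshold)
            if resp is not None:
                rt = state.t_in_trial_ms - onset + config.motor_delay_ms
                result = TrialResult(
                    trial_index=trial.index,
                    response=resp,
                    rt_ms=rt,
                    correct=resp == correct_side,
                    integrated_cost=cost,
                    timeout=False,
                )
                return post_response_reset(state, config), result, trace
            if state.t_in_trial_ms - onset >= config.timeout_ms:
                result = TrialResult(
                    trial_index=trial.index,
                    response=None,
                    rt_ms=None,
                    correct=None,
                    integrated_cost=cost,
                    timeout=True,
                )
                return post_response_reset(state, config), result, trace


def trace_to_frame(trace: Sequence[TraceRecord]) -> pd.DataFrame:
    """Tidy per-tick trace: one row per (tick, channel, label) with the
    density weight, the goal weight, and the step cost."""
    rows = []
    for rec in trace:
        for channel in CHANNELS:
            d = rec.densities[channel]
            g = rec.goals[channel]
            for lab in d.labels:
                rows.append(
                    {
                        "tick_ms": rec.t_ms,
                        "phase": rec.phase,
                        "channel": channel,
                        "label": lab,
                        "weight": d[lab],
                        "goal_weight": g[lab],
                        "step_cost": rec.step_cost,
                        "goal_cost": rec.goal_cost,
                    }
                )
    return pd.DataFrame(rows)
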