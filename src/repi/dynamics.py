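"""Resource-limited density updates and goal-density constructors.

The heart of the model is a single update rule: at every iteration each
channel's density is pulled toward its current goal density under a fixed
per-step resource budget,

    Q(X) = normalize( P(X) + alpha * epsilon * G(X) ),

where ``alpha`` is a rate factor per iteration and ``epsilon`` the
cognitive resources available per step.  Since P and G each sum to one
this is the affine mixture ``(P + c G) / (1 + c)`` with ``c = alpha *
epsilon``, so each step contracts the total-variation distance to the
goal by exactly ``1 / (1 + c)``.

The goal constructors below define, for each of the five channels
(observation, stimulus-side bias, task set, response side, response),
what the ideal target density is at a given moment of a trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .densities import DiscreteDensity, _trusted, soft_one_hot, uniform_density

__all__ = [
    "UpdateParams",
    "TaskMapping",
    "LatentConfig",
    "step_update",
    "task_goal",
    "observation_goal",
    "bias_goal",
    "response_side_goal",
    "response_goal",
    "LATENT_TASK",
]

#: Reserved label for the habitual (latent) stimulus-side -> response-side
#: channel; always the last entry of the task space.
LATENT_TASK = "latent"


@dataclass(frozen=True)
class UpdateParams:
    """Resource parameters of the per-iteration update rule.

    alpha
        Rate factor per iteration; with a 10 ms step, ``alpha = 0.01``
        expresses per-second resources on a per-iteration scale.
    epsilon
        Cognitive resource rate (per second, dimensionless).
    dt_ms
        Simulated milliseconds per iteration.
    """

    alpha: float = 0.01
    epsilon: float = 6.0
    dt_ms: float = 10.0

    def __post_init__(self):
        if self.alpha <= 0 or self.epsilon <= 0 or self.dt_ms <= 0:
            raise ValueError("alpha, epsilon and dt_ms must all be positive")

    @property
    def c(self) -> float:
        """Per-step goal gain ``alpha * epsilon`` (default 0.06)."""
        return self.alpha * self.epsilon


@dataclass(frozen=True)
class TaskMapping:
    """A task's column-stochastic object -> response-side mapping matrix.

    ``matrix[i, j]`` is the probability that object ``object_labels[j]``
    maps onto response side ``side_labels[i]`` under this task; every
    column sums to 1.
    """

    task_label: str
    side_labels: tuple
    object_labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.side_labels), len(self.object_labels)):
            raise ValueError("matrix shape must be (n_sides, n_objects)")
        if np.any(m < 0) or not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("matrix columns must be non-negative and sum to 1")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "side_labels", tuple(self.side_labels))
        object.__setattr__(self, "object_labels", tuple(self.object_labels))

    def map_object(self, obj_label: str) -> str:
        """Deterministic response side for one object (argmax of its column)."""
        col = self.matrix[:, self.object_labels.index(obj_label)]
        return self.side_labels[int(np.argmax(col))]

    def apply(self, obs: DiscreteDensity) -> np.ndarray:
        """Push an observation density through the mapping (raw weights)."""
        if obs.labels != self.object_labels:
            raise ValueError("observation labels do not match mapping objects")
        return self.matrix @ obs.weights


@dataclass(frozen=True)
class LatentConfig:
    """Latent/habitual activity levels and goal-signal strengths.

    lambda_iti
        Latent task activity while no fixation cross or cue is on screen
        (inter-trial / response-cue interval).
    lambda_active
        Latent activity from fixation or cue onset through the response.
    cue_strength
        Goal mass placed on the cued task once the cue (or fixation
        cross, when the task is fixed) is visible; the remainder
        ``1 - cue_strength`` stays on the latent channel.
    stimulus_mass
        Goal mass on the presented object once the imperative stimulus
        is visible; the small remainder models a slim chance of
        misperceiving one of the other objects.
    side_mass
        Goal mass on the stimulus side in the bias channel for lateral
        stimuli (mirrors ``stimulus_mass`` by default).
    bias_evidence_weight
        How strongly a lateral stimulus' side evidence enters the bias
        goal, relative to the anticipated-response feedback the channel
        tracks otherwise.  1 would pin the bias to the stimulus side —
        which freezes the incompatible response-side equilibrium just
        below the response threshold and stalls responding — so the two
        signals are mixed evenly by default.
    """

    lambda_iti: float = 0.2
    lambda_active: float = 0.1
    cue_strength: float = 0.9
    stimulus_mass: float = 0.97
    side_mass: float = 0.97
    bias_evidence_weight: float = 0.5

    def __post_init__(self):
        for name in ("lambda_iti", "lambda_active", "cue_strength",
                     "stimulus_mass", "side_mass", "bias_evidence_weight"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def step_update(
    prior: DiscreteDensity, goal: DiscreteDensity, params: UpdateParams
) -> DiscreteDensity:
    """One resource-limited update of ``prior`` toward ``goal``.

    Returns ``normalize(P + c G)`` with ``c = alpha * epsilon``; both
    operands sum to one so the normalizer is exactly ``1 + c``.
    """
    if prior.labels != goal.labels:
        raise ValueError("prior and goal must share labels")
    c = params.c
    return _trusted(prior.labels, (prior.weights + c * goal.weights) / (1.0 + c))


def task_goal(
    task_labels: Sequence[str],
    cued: Optional[str],
    prepared_set: Sequence[str],
    latent_level: float,
    cue_strength: float,
) -> DiscreteDensity:
    """Goal density over the task space.

    With a visible cue, ``cue_strength`` goes on the cued task and the
    remainder on the latent channel.  Without a cue the goal expresses
    readiness for all prepared tasks: ``(1 - latent_level)`` split evenly
    over the prepared set, ``latent_level`` on the latent channel, and
    zero on any dormant task slots.
    """
    return _task_goal_cached(
        tuple(task_labels), cued, tuple(prepared_set),
        float(latent_level), float(cue_strength),
    )


@lru_cache(maxsize=512)
def _task_goal_cached(
    task_labels: tuple,
    cued: Optional[str],
    prepared_set: tuple,
    latent_level: float,
    cue_strength: float,
) -> DiscreteDensity:
    if task_labels[-1] != LATENT_TASK:
        raise ValueError(f"last task label must be {LATENT_TASK!r}")
    w = np.zeros(len(task_labels))
    if cued is not None:
        if cued not in task_labels[:-1]:
            raise ValueError(f"unknown cued task {cued!r}")
        w[task_labels.index(cued)] = cue_strength
        w[-1] = 1.0 - cue_strength
    else:
        prepared = tuple(prepared_set)
        unknown = set(prepared) - set(task_labels[:-1])
        if unknown:
            raise ValueError(f"unknown prepared tasks {unknown}")
        if prepared:
            for t in prepared:
                w[task_labels.index(t)] = (1.0 - latent_level) / len(prepared)
            w[-1] = latent_level
        else:
            w[-1] = 1.0
    return DiscreteDensity(task_labels, w)


def observation_goal(
    stimulus_visible: bool,
    presented_object: Optional[str],
    object_labels: Sequence[str],
    task_density: DiscreteDensity,
    stimulus_mass: float,
) -> DiscreteDensity:
    """Goal density over the object space.

    With the imperative stimulus on screen, bottom-up evidence dominates:
    a soft one-hot on the presented object.  Beforehand the goal is the
    top-down stimulus expectation given the current task set; with the
    default crossed stimulus set every object is relevant to every task,
    so this expectation is uniform.
    """
    if stimulus_visible:
        if presented_object is None:
            raise ValueError("visible stimulus requires a presented object")
        return soft_one_hot(tuple(object_labels), presented_object, stimulus_mass)
    return uniform_density(tuple(object_labels))


def bias_goal(
    lateral_side: Optional[str],
    side_labels: Sequence[str],
    response_side_density: DiscreteDensity,
    side_mass: float,
    evidence_weight: float = 0.5,
) -> DiscreteDensity:
    """Goal density over the stimulus-side bias space.

    With a central (or no) stimulus there is no side evidence: the bias
    tracks the current response-side density, feeding anticipated
    response consequences back into the habitual channel.  A lateral
    stimulus adds side evidence (a soft one-hot with ``side_mass`` on
    the stimulus side) mixed with that feedback at ``evidence_weight``;
    ``evidence_weight = 1`` pins the goal to the stimulus side alone.
    """
    side_labels = tuple(side_labels)
    if response_side_density.labels != side_labels:
        raise ValueError("response-side density labels do not match sides")
    if lateral_side is None:
        return response_side_density
    if lateral_side not in side_labels:
        raise ValueError(f"unknown side {lateral_side!r}")
    if not (0.0 <= evidence_weight <= 1.0):
        raise ValueError("evidence_weight outside [0, 1]")
    evidence = soft_one_hot(side_labels, lateral_side, side_mass)
    if evidence_weight == 1.0:
        return evidence
    w = (
        evidence_weight * evidence.weights
        + (1.0 - evidence_weight) * response_side_density.weights
    )
    return _trusted(side_labels, w)


def response_side_goal(
    obs: DiscreteDensity,
    task: DiscreteDensity,
    bias: DiscreteDensity,
    mappings: Sequence[TaskMapping],
) -> DiscreteDensity:
    """Goal over response sides: task-weighted mappings plus latent bias.

    Each task's mapping matrix pushes the observation density onto
    response sides, weighted by that task's activity; the latent task
    activity adds the stimulus-side bias density.  The mixture is
    renormalized (a no-op unless dormant tasks carry mass).
    """
    for m in mappings:
        if m.task_label not in task.labels:
            raise ValueError(f"task density lacks mapping task {m.task_label!r}")
    if task.labels[-1] != LATENT_TASK:
        raise ValueError(f"task density must end with {LATENT_TASK!r}")
    w = task[LATENT_TASK] * bias.weights
    for m in mappings:
        w = w + task[m.task_label] * m.apply(obs)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate response-side goal (no active channel)")
    return _trusted(bias.labels, w / total)


def response_goal(
    stimulus_onset_passed: bool,
    side_density: DiscreteDensity,
    response_labels: Sequence[str],
) -> DiscreteDensity:
    """Goal over overt responses: uniform before stimulus onset, then a
    copy of the current processing-side density."""
    response_labels = tuple(response_labels)
    if not stimulus_onset_passed:
        return uniform_density(response_labels)
    if side_density.labels != response_labels:
        raise ValueError("side and response labels must align")
    return side_density
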