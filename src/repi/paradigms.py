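"""Seeded trial sequences and phase schedules for the two paradigms.

The stimulus set is the full cross of two forms (star, circle) and two
colors (black, white).  In the Simon paradigm the task is always to
respond to form while the stimulus may appear left, center or right of
fixation; in the task-switching paradigm a per-trial cue selects the
form or the color task and all stimuli are central.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "FORMS",
    "COLORS",
    "SIDES",
    "OBJECT_LABELS",
    "StimulusObject",
    "TrialSchedule",
    "Trial",
    "ParadigmConfig",
    "generate_simon_trials",
    "generate_switching_trials",
    "phase_at",
    "trials_to_csv",
    "trials_from_csv",
]

FORMS = ("star", "circle")
COLORS = ("black", "white")
SIDES = ("left", "right")  # response / bias sides
STIMULUS_POSITIONS = ("left", "center", "right")


@dataclass(frozen=True)
class StimulusObject:
    """One of the four stimuli: a form-color combination."""

    form: str
    color: str

    def __post_init__(self):
        if self.form not in FORMS or self.color not in COLORS:
            raise ValueError(f"unknown stimulus {self.color} {self.form}")

    @property
    def label(self) -> str:
        return f"{self.color}_{self.form}"

    @classmethod
    def from_label(cls, label: str) -> "StimulusObject":
        color, form = label.split("_")
        return cls(form=form, color=color)


#: Ordered object space used by every density and mapping matrix.
OBJECT_LABELS = tuple(
    StimulusObject(form=f, color=c).label for c in COLORS for f in FORMS
)


@dataclass(frozen=True)
class TrialSchedule:
    """Phase onsets in ms from trial start (all multiples of dt).

    The leading interval doubles as the inter-trial interval (Simon) or
    the response-cue interval (switching); the fixation cross or task
    cue appears at its end, and the imperative stimulus after the
    fixation-stimulus or cue-stimulus interval.
    """

    iti_ms: float
    stimulus_onset_ms: float

    @property
    def cue_onset_ms(self) -> float:
        return self.iti_ms

    def __post_init__(self):
        if not (0 < self.iti_ms < self.stimulus_onset_ms):
            raise ValueError("need 0 < iti < stimulus onset")


@dataclass(frozen=True)
class Trial:
    """One experimental trial: cued task, stimulus identity and position."""

    index: int
    cued_task: str
    obj: StimulusObject
    side: str  # left | center | right
    schedule: TrialSchedule

    def __post_init__(self):
        if self.side not in STIMULUS_POSITIONS:
            raise ValueError(f"unknown stimulus position {self.side!r}")

    @property
    def lateral_side(self) -> Optional[str]:
        """The stimulus side if lateral, else None for central stimuli."""
        return self.side if self.side in SIDES else None


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial-sequence parameters shared by both paradigms.

    Timings are in ms and must be positive multiples of the simulation
    step.  ``fixation_to_stimulus_ms`` applies to the Simon paradigm,
    ``csi_ms`` (cue-stimulus interval) and ``rci_ms`` (response-cue
    interval) to task switching.
    """

    n_trials: int = 200
    seed: int = 0
    iti_ms: float = 100.0
    fixation_to_stimulus_ms: float = 500.0
    csi_ms: float = 100.0
    rci_ms: float = 100.0
    switch_probability: float = 0.5
    side_positions: Sequence[str] = STIMULUS_POSITIONS
    side_probabilities: Optional[Sequence[float]] = None  # default uniform

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not (0.0 <= self.switch_probability <= 1.0):
            raise ValueError("switch_probability outside [0, 1]")
        for name in ("iti_ms", "fixation_to_stimulus_ms", "csi_ms", "rci_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "side_positions", tuple(self.side_positions))


def _substreams(seed: int, n: int) -> list:
    """Independent per-factor generator streams split from one seed, so a
    change in how one factor is drawn never shifts the others."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_objects(rng: np.random.Generator, n: int) -> List[StimulusObject]:
    labels = rng.choice(len(OBJECT_LABELS), size=n)
    return [StimulusObject.from_label(OBJECT_LABELS[i]) for i in labels]


def generate_simon_trials(config: ParadigmConfig) -> List[Trial]:
    """Seeded Simon sequence: form task throughout, object uniform over
    the four stimuli, position uniform over left/center/right."""
    obj_rng, side_rng, _ = _substreams(config.seed, 3)
    schedule = TrialSchedule(
        iti_ms=config.iti_ms,
        stimulus_onset_ms=config.iti_ms + config.fixation_to_stimulus_ms,
    )
    objects = _draw_objects(obj_rng, config.n_trials)
    p = config.side_probabilities
    sides = side_rng.choice(config.side_positions, size=config.n_trials, p=p)
    return [
        Trial(index=i, cued_task="form", obj=o, side=str(s), schedule=schedule)
        for i, (o, s) in enumerate(zip(objects, sides))
    ]


def generate_switching_trials(config: ParadigmConfig) -> List[Trial]:
    """Seeded task-switching sequence: central stimuli, cued task
    alternating with ``switch_probability`` per trial (first task drawn
    uniformly), object uniform over the four stimuli."""
    obj_rng, _, task_rng = _substreams(config.seed, 3)
    schedule = TrialSchedule(
        iti_ms=config.rci_ms,
        stimulus_onset_ms=config.rci_ms + config.csi_ms,
    )
    objects = _draw_objects(obj_rng, config.n_trials)
    tasks: List[str] = []
    current = ("form", "color")[int(task_rng.integers(2))]
    for _ in range(config.n_trials):
        tasks.append(current)
        if task_rng.random() < config.switch_probability:
            current = "color" if current == "form" else "form"
    return [
        Trial(index=i, cued_task=t, obj=o, side="center", schedule=schedule)
        for i, (o, t) in enumerate(zip(objects, tasks))
    ]


def phase_at(trial: Trial, t_ms: float) -> str:
    """Trial phase at time ``t_ms`` from trial start.

    Intervals are half-open ``[onset, next_onset)``; the stimulus phase
    begins exactly at stimulus onset and lasts until the response (which
    the simulation engine, not the schedule, decides).
    """
    if t_ms < 0:
        raise ValueError("negative trial time")
    s = trial.schedule
    if t_ms < s.iti_ms:
        return "iti"
    if t_ms < s.stimulus_onset_ms:
        return "fixation_or_cue"
    return "stimulus"


# -- CSV round-trip so identical sequences can be replayed across
# -- model variants (e.g. full vs instant-perception dynamics). --------

_CSV_FIELDS = ("index", "task", "form", "color", "side", "iti_ms", "stimulus_onset_ms")


def trials_to_csv(trials: Iterable[Trial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for t in trials:
            w.writerow(
                [t.index, t.cued_task, t.obj.form, t.obj.color, t.side,
                 t.schedule.iti_ms, t.schedule.stimulus_onset_ms]
            )


def trials_from_csv(path) -> List[Trial]:
    out: List[Trial] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Trial(
                    index=int(row["index"]),
                    cued_task=row["task"],
                    obj=StimulusObject(form=row["form"], color=row["color"]),
                    side=row["side"],
                    schedule=TrialSchedule(
                        iti_ms=float(row["iti_ms"]),
                        stimulus_onset_ms=float(row["stimulus_onset_ms"]),
                    ),
                )
            )
    return out
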