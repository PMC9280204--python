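"""Seeded experiment batches, condition labeling and RT/cost summaries.

An *experiment* is one seeded sequence of trials run through the model
with state carried across trials, so residual density activity from one
trial shapes the next.  A *batch* pools several independent experiments
(fresh state, consecutive seeds).  Condition labels are attached per
paradigm — stimulus-response compatibility and response repetition for
the Simon task; task transition, congruency, previous response side and
object repetition for task switching — and summaries report mean RT,
its standard error, the trial count and the mean integrated cost per
condition over correct, non-omission trials.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelConfig, TrialResult, init_state, run_trial
from .paradigms import (
    ParadigmConfig,
    Trial,
    generate_simon_trials,
    generate_switching_trials,
)

__all__ = [
    "run_trials",
    "run_experiment",
    "run_batch",
    "label_conditions",
    "summarize",
    "welch_p",
]

_GENERATORS = {
    "simon": generate_simon_trials,
    "switching": generate_switching_trials,
}

#: Default grouping keys per paradigm, mirroring the reported contrasts.
GROUPING_KEYS = {
    "simon": ["compatibility", "response_repetition"],
    "switching": ["transition", "congruency", "prev_response_side"],
}


def _task_maps(config: ModelConfig) -> dict:
    return {m.task_label: m for m in config.mappings}


def run_trials(
    model_config: ModelConfig, trials: Sequence[Trial]
) -> List[TrialResult]:
    """Run an explicit trial sequence from a fresh resting state,
    carrying model state across trials."""
    state = init_state(model_config)
    results: List[TrialResult] = []
    for trial in trials:
        state, result, _ = run_trial(state, trial, model_config)
        results.append(result)
    return results


def run_experiment(
    model_config: ModelConfig,
    paradigm_config: ParadigmConfig,
    paradigm: str,
    seed: Optional[int] = None,
) -> Tuple[List[Trial], List[TrialResult]]:
    """Generate one seeded trial sequence and run it; deterministic given
    the configurations and seed."""
    if paradigm not in _GENERATORS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if seed is not None:
        paradigm_config = replace(paradigm_config, seed=seed)
    trials = _GENERATORS[paradigm](paradigm_config)
    return trials, run_trials(model_config, trials)


def run_batch(
    model_config: ModelConfig,
    paradigm_config: ParadigmConfig,
    paradigm: str,
    n_experiments: int = 20,
    base_seed: int = 0,
    trials_per_experiment: Optional[Sequence[Sequence[Trial]]] = None,
) -> pd.DataFrame:
    """Pool ``n_experiments`` independent experiments (seeds
    ``base_seed + i``) into one labeled trial-level table.

    ``trials_per_experiment`` replays explicit trial sequences instead
    of generating them — the hook for comparing model variants on
    identical inputs.
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    frames = []
    for i in range(n_experiments):
        if trials_per_experiment is not None:
            trials = list(trials_per_experiment[i])
            results = run_trials(model_config, trials)
        else:
            trials, results = run_experiment(
                model_config, paradigm_config, paradigm, seed=base_seed + i
            )
        records = label_conditions(trials, results, paradigm, model_config)
        df = pd.DataFrame.from_records(records)
        df.insert(0, "experiment", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def label_conditions(
    trials: Sequence[Trial],
    results: Sequence[TrialResult],
    paradigm: str,
    model_config: Optional[ModelConfig] = None,
) -> List[dict]:
    """Attach per-trial condition labels to aligned trial/result pairs.

    Simon labels: ``compatibility`` (stimulus side vs correct response
    side; central stimuli are neutral) and ``response_repetition``.
    Switching labels: ``transition`` (task switch vs repeat),
    ``congruency`` (whether the currently irrelevant task maps the
    stimulus onto the same response side), ``prev_response_side`` and
    ``object_repetition``.  First trials (or trials after an omission)
    carry the label ``first`` in history-dependent contrasts.
    """
    if len(trials) != len(results):
        raise ValueError("trials and results must be aligned")
    if paradigm not in _GENERATORS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    maps = _task_maps(model_config if model_config is not None else ModelConfig())

    records: List[dict] = []
    prev: Optional[Trial] = None
    prev_response: Optional[str] = None
    for trial, result in zip(trials, results):
        correct_side = maps[trial.cued_task].map_object(trial.obj.label)
        rec = {
            "trial": trial.index,
            "task": trial.cued_task,
            "form": trial.obj.form,
            "color": trial.obj.color,
            "side": trial.side,
            "correct_side": correct_side,
            "response": result.response,
            "rt_ms": result.rt_ms,
            "correct": result.correct,
            "cost": result.integrated_cost,
            "timeout": result.timeout,
        }
        if paradigm == "simon":
            if trial.lateral_side is None:
                rec["compatibility"] = "neutral"
            elif trial.lateral_side == correct_side:
                rec["compatibility"] = "compatible"
            else:
                rec["compatibility"] = "incompatible"
            if prev_response is None or result.response is None:
                rec["response_repetition"] = "first"
            else:
                rec["response_repetition"] = (
                    "same" if result.response == prev_response else "different"
                )
        else:
            other = "color" if trial.cued_task == "form" else "form"
            rec["congruency"] = (
                "congruent"
                if maps[other].map_object(trial.obj.label) == correct_side
                else "incongruent"
            )
            rec["transition"] = (
                "first"
                if prev is None
                else ("repeat" if trial.cued_task == prev.cued_task else "switch")
            )
            if prev_response is None or result.response is None:
                rec["prev_response_side"] = "first"
            else:
                rec["prev_response_side"] = (
                    "same" if result.response == prev_response else "other"
                )
            rec["object_repetition"] = (
                "first"
                if prev is None
                else ("same" if trial.obj == prev.obj else "different")
            )
        records.append(rec)
        prev = trial
        prev_response = result.response
    return records


def summarize(
    records: pd.DataFrame, grouping_keys: Sequence[str]
) -> pd.DataFrame:
    """Condition summary over correct, non-omission trials: mean RT (ms),
    its standard error, the trial count and the mean integrated cost.

    Singleton groups report SE 0 (flagged by ``n == 1``); groups emptied
    by the correctness filter are dropped with a warning.
    """
    keys = list(grouping_keys)
    included = records[(records["correct"] == True) & (~records["timeout"])]  # noqa: E712
    if included.empty:
        raise ValueError("no correct, non-omission trials to summarize")
    n_groups_all = records.groupby(keys, observed=True).ngroups
    grouped = included.groupby(keys, observed=True)
    if grouped.ngroups < n_groups_all:
        warnings.warn("some condition groups had no includable trials; rows omitted")
    out = grouped.agg(
        mean_rt_ms=("rt_ms", "mean"),
        se_rt_ms=("rt_ms", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0),
        n=("rt_ms", "size"),
        mean_cost=("cost", "mean"),
    )
    return out.reset_index()


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch two-sample t-test p-value for an RT/cost contrast."""
    return float(stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False).pvalue)
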