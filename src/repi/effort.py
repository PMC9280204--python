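"""Cognitive-effort measures: per-tick information costs and integrals.

Two per-tick measures of the effort invested in the response-side space
are provided:

``step_task_cost``
    The divergence between the response-side goal and its prior,
    ``KL(G(S) || P(S))`` — the immediate refocusing demand.  It vanishes
    once the channels settle into their joint fixed point.

``step_evidence_cost``
    The evidence-weighted mean cost: for every (task, object) belief
    pair the cost of refocusing the response-side prior onto the
    response that pair implies, weighted by the current task and
    observation beliefs, plus the latent channel's term with the bias
    density as its implied response,

        sum_{psi,o} p(psi) p(o) KL(Q(S | psi, o) || P(S)).

    This is a mutual information between the (task, object) evidence
    and the response side.  Unlike the goal divergence it stays positive
    at equilibrium whenever residual beliefs keep implying a different
    response than the prior holds — sustained response conflict keeps
    costing — which is why it serves as the headline trial cost.

The integrated trial cost sums the per-tick measure from stimulus onset
through the response tick, in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .densities import PROB_FLOOR, DiscreteDensity, kl_divergence
from .dynamics import LATENT_TASK, TaskMapping

__all__ = [
    "TrialCost",
    "step_task_cost",
    "step_evidence_cost",
    "integrate_trial_cost",
    "investment_cost",
    "channel_step_costs",
]


@dataclass(frozen=True)
class TrialCost:
    """Per-tick costs (nats) and their sum over the integration window."""

    per_tick_costs: tuple
    integrated_cost: float
    timed_out: bool = False


def step_task_cost(
    side_goal: DiscreteDensity, side_prior: DiscreteDensity
) -> float:
    """One tick's goal-divergence cost: ``KL(G(S) || P(S))`` in nats."""
    return kl_divergence(side_goal, side_prior)


def step_evidence_cost(
    obs: DiscreteDensity,
    task: DiscreteDensity,
    bias: DiscreteDensity,
    side_prior: DiscreteDensity,
    mappings: Sequence[TaskMapping],
) -> float:
    """Evidence-weighted refocusing cost of one tick, in nats.

    For each mapped task the implied response given object ``o`` is the
    mapping's column; for the latent task it is the current bias
    density.  Each implied response is compared to the response-side
    prior by KL and weighted by the current beliefs ``p(psi) p(o)``.
    """
    logp = np.log(np.maximum(side_prior.weights, PROB_FLOOR))
    cost = 0.0
    for m in mappings:
        w_task = task[m.task_label]
        if w_task == 0.0:
            continue
        cols = m.matrix  # (n_sides, n_objects), columns sum to 1
        # sum_o p(o) KL(col_o || P)  =  sum_o p(o) H-term(col_o) - logp . (M p_o)
        neg_entropy = np.where(
            cols > 0.0, cols * np.log(np.where(cols > 0.0, cols, 1.0)), 0.0
        ).sum(axis=0)
        # np.sum reductions (not BLAS dot) keep the result bit-exact
        # under a left/right mirror of all side-indexed quantities
        cost += w_task * float(
            np.sum(neg_entropy * obs.weights) - np.sum(logp * (cols @ obs.weights))
        )
    w_lat = task[LATENT_TASK]
    if w_lat > 0.0:
        cost += w_lat * kl_divergence(bias, side_prior)
    return cost


def investment_cost(prior: DiscreteDensity, posterior: DiscreteDensity) -> float:
    """Cost of changing ``prior`` into ``posterior``: KL(posterior || prior)."""
    return kl_divergence(posterior, prior)


def integrate_trial_cost(
    trace: Sequence,
    stimulus_onset_tick: int,
    response_tick: int,
    timed_out: bool = False,
) -> TrialCost:
    """Sum per-tick costs over ticks ``[stimulus_onset_tick, response_tick]``
    (inclusive), indices into a recorded trace.

    For omission trials pass the timeout tick as ``response_tick`` and
    set ``timed_out`` so the cost is flagged as censored.
    """
    if not (0 <= stimulus_onset_tick <= response_tick < len(trace)):
        raise ValueError("integration window outside the recorded trace")
    per_tick = tuple(
        rec.step_cost for rec in trace[stimulus_onset_tick : response_tick + 1]
    )
    return TrialCost(per_tick, float(sum(per_tick)), timed_out)


def channel_step_costs(trace: Sequence) -> List[dict]:
    """Per-tick ``KL(G(X) || P(X))`` for every channel (exploratory hook;
    the headline cost concerns only the response-side space).

    Priors are the pre-update densities, i.e. the previous record's
    post-update densities; the first record is skipped.
    """
    out: List[dict] = []
    for prev, rec in zip(trace, trace[1:]):
        row = {"t_ms": rec.t_ms}
        for ch in ("obs", "bias", "task", "side", "response"):
            row[ch] = kl_divergence(rec.goals[ch], prev.densities[ch])
        out.append(row)
    return out
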