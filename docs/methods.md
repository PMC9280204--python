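# Methods

## Model overview

The simulator treats trial-by-trial cognition as goal-directed density
dynamics under a resource budget.  All beliefs are labeled discrete
probability densities; five of them are wired into an architecture:

| channel | space | role |
|---------|-------|------|
| `obs` (*O*) | 4 objects (black/white × star/circle) | perceptual evidence accumulation |
| `bias` (*B*) | left / right | irrelevant stimulus-side information and anticipated response consequences |
| `task` (*Ψ*) | form, color, (dormant…), latent | task-set activation; the latent slot is the habitual side→response channel |
| `side` (*S*) | left / right | response-side selection |
| `response` (*R*) | left / right | overt-response accumulation to threshold |

Each 10 ms tick every channel takes one step of

    Q(X) = normalize( P(X) + α ε G(X) ),   α = 0.01, ε = 6,

toward its current goal density G(X).  Both operands are densities, so
the normalizer is exactly 1 + αε and one step contracts the
total-variation distance to the goal by 1/(1 + αε) ≈ 0.943.  The goals
are computed synchronously from the pre-update state (a Jacobi sweep),
so channel evaluation order cannot affect results.  From a uniform
two-category prior toward a hard one-hot goal the leading weight first
reaches 0.9 at iteration 28 (scalar recurrence `1 − 0.5 (1+αε)^(−t)`),
i.e. a fully prepared choice takes ≈ 280 ms of accumulation — the basic
time scale of the model.

Goal definitions per phase of a trial:

- **task**: during the inter-trial / response–cue interval, readiness
  over the prepared task set with latent level λ_ITI = 0.2
  (`[(1−λ)/k, …, 0, λ]`, dormant slots always 0); from fixation/cue
  onward, 0.9 on the cued task and 0.1 on the latent channel.
- **obs**: before stimulus onset, the top-down expectation given the
  task set — uniform under the default crossed stimulus set, where every
  object is relevant to every task (a per-task object-prior table can
  generalize this); from onset, a soft one-hot with 0.97 on the
  presented object (each other object keeps a 0.01 misperception
  chance).
- **bias**: with no lateral stimulus, a copy of the current
  response-side density (anticipated response consequences fed back);
  with a lateral stimulus, that feedback mixed 50/50 with side evidence
  (soft one-hot, mass 0.97 on the stimulus side).  See *Design
  decisions* below.
- **side**: the task-weighted mixture Σ_ψ p(ψ)·(M_ψ · obs) plus
  p(latent)·bias, renormalized.  M_form maps stars left and circles
  right; M_color maps black left and white right; matrices are
  column-stochastic and configurable.
- **response**: uniform until stimulus onset (no activity is passed on
  before the imperative stimulus), then a copy of the current side
  density.

A response triggers at the first tick where the maximal response weight
reaches θ_r = 0.9 (inclusive; ties cannot occur above 0.5).  RT is the
time from stimulus onset to that tick; an optional additive motor delay
defaults to 0.  After the response (or a 5000 ms timeout, recorded as
an omission), `side` and `response` snap back to uniform while `obs`,
`bias` and `task` persist — residual activity is what produces switch
costs, congruency effects and response-repetition benefits on later
trials.

## Effort measures

Two per-tick measures of response-side effort are computed, both in
nats (natural log throughout; no log base is privileged by the theory,
and a base-2 report is a constant factor):

1. **Goal divergence** `KL(G(S) ‖ P(S))` — the immediate refocusing
   demand.  It decays to zero as the coupled channels settle into their
   joint fixed point, so it measures transient adaptation only.
2. **Evidence-weighted cost** (headline)
   `Σ_{ψ,o} p(ψ)p(o) KL(Q(S|ψ,o) ‖ P(S))`, where `Q(S|ψ,o)` is the
   mapping column for mapped tasks and the bias density for the latent
   channel.  This is the mutual information between the (task, object)
   evidence and the response side.  It remains positive at equilibrium
   whenever residual beliefs still imply a different response than the
   prior holds, so sustained response conflict — e.g. a latent channel
   pointing at the wrong side throughout an incompatible trial — keeps
   accruing cost.

The integrated trial cost sums the per-tick measure from stimulus onset
through the response tick inclusive (omissions: through the timeout
tick, flagged as censored).  Measure 2 is the headline because only it
reproduces the empirical coupling that slower, more conflicted
conditions are also the more effortful ones; with measure 1 the
ordering across Simon conditions inverts (fast compatible trials travel
further in KL per unit time than slow near-threshold incompatible
ones).  Both are recorded in traces (`step_cost`, `goal_cost`).  A
hook (`repi.effort.channel_step_costs`) exposes the same divergence for
the other channels, but the reported cost concerns the response-side
space only.

## Paradigms (what the trial generator emulates)

- **Simon**: 100 ms inter-trial interval, fixation cross, imperative
  stimulus 500 ms later.  The task is always form; objects are uniform
  over the four stimuli and the stimulus position uniform over
  left/center/right (the true proportions of central vs lateral trials
  in such experiments vary; uniform thirds is the neutral choice).
  Compatibility is stimulus side vs correct response side; central
  trials are neutral.
- **Task switching**: response–cue interval 100 ms, cue–stimulus
  interval 100 ms (500 ms in the preparation manipulation), all stimuli
  central, the cued task switching with probability 0.5 per trial,
  independently sampled (no counterbalancing).  Congruency is whether
  the currently irrelevant task maps the stimulus onto the same
  response side.

Each experiment is 200 trials; batches pool 20 independent experiments
(fresh initial state, consecutive seeds).  One seed-sequence stream per
experiment is split into object/side/task substreams, so changing how
one factor is drawn never shifts the others.  These sizes keep every
full-scale behavioral check within a few minutes on one CPU while
leaving standard errors on condition means near 1 ms.

What the generator deliberately does **not** emulate: sequential
expectation or fatigue effects, error-driven slowing, predictable or
voluntary task switching, go/no-go designs, non-uniform side
proportions.  Passing checks therefore show that the architecture
produces the canonical within-session condition contrasts, not that it
fits any particular empirical data set.

## Design decisions

- **Bias evidence/feedback mixing.**  With the latent task activity at
  0.1 and a stimulus goal of 0.97, a bias goal pinned entirely to the
  side of a lateral stimulus freezes the incompatible response-side
  equilibrium at 0.9·0.98 + 0.1·0.03 = 0.885 — just below the response
  threshold — so incompatible trials would never respond.  The bias
  goal therefore mixes side evidence with the response-side feedback at
  equal weight (`bias_evidence_weight = 0.5`, configurable), giving an
  incompatible equilibrium ≈ 0.93: crossings happen, but slowly, which
  *is* the model's account of the Simon effect.
- **Latent-level coupling in the ablation.**  `with_latent_level(x)`
  sets both latent activity values to *x* and the cue goal to 1 − *x*
  on the cued task, so `x = 0` removes the habitual channel entirely;
  the Simon effect then vanishes (the residual task-density latent mass
  decays geometrically and is sub-tick within two trials).
- **Task goal while solving.**  By default the cue goal (0.9 cued / 0.1
  latent) persists through the stimulus phase, reading the latent
  activity as "0.1 once fixation or stimulus is shown".  A
  `focus_task_when_solving` switch instead drives the task goal to a
  one-hot on the cued task from stimulus onset; it produces the same
  qualitative pattern with much smaller Simon margins and is off by
  default.
- **Feedback source.**  The anticipated-consequence feedback into the
  bias channel copies the response-side density (`side`); copying the
  overt response density instead (`bias_feedback_source="response"`)
  behaves near-identically and is kept as a configuration option.
- **Exclusions.**  Error responses and omissions are excluded from RT
  and cost summaries but counted; the first trial of each experiment is
  labeled `first` in history-dependent contrasts.  Standard errors are
  computed across pooled trials within a condition.
- **Effect-direction checks** use two-sided Welch two-sample t-tests on
  pooled trials at p < 0.01 — a deterministic pass rule for direction,
  not a claim about empirical effect sizes.

## Numerical choices

- Densities validate non-negativity and sum-to-one (|Σw − 1| ≤ 1e-9) at
  construction; updates renormalize analytically, so normalization
  holds at every tick.
- Inside KL the reference density is floored at 1e-12 so hard one-hot
  goals stay finite; terms with zero posterior mass contribute 0.
- Scalar reductions in the cost kernel use elementwise multiply +
  `np.sum` rather than BLAS dot products: FMA-based dots are not
  invariant under operand reversal, and the left↔right mirror symmetry
  of the whole simulation is maintained bit-exactly (and tested).
- Threshold comparison is inclusive (≥ θ_r); argmax ties break by label
  order but cannot occur for θ_r > 0.5.
- All timings are multiples of the 10 ms tick; phase intervals are
  half-open `[onset, next_onset)`.
- Densities are immutable values; every update returns a new density,
  which makes traces trivially recordable and tests order-independent.

## Known limitations

- The two effort measures disagree about condition ordering by
  construction (see above); the goal-divergence measure is retained for
  analysis but should not be integrated as a trial cost.
- Incompatible Simon reaction times are long relative to compatible
  ones because the incompatible equilibrium sits near the response
  threshold; the model captures the direction and the RT–cost coupling
  of the effect, not empirical effect magnitudes.
- No prospective planning, no learning of mapping matrices, no adaptive
  (non-uniform) resource allocation across channels: the resource rate
  ε is constant over channels and time, with a per-channel override
  hook left unused by default.
- Motor execution is instantaneous at threshold; omissions are the only
  failure mode besides wrong-side responses.
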