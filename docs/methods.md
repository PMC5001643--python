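# Methods

## The model

Behavior on two-stage decision tasks is modeled by a hybrid agent with
two valuation systems.

**Model-free system.** A SARSA(λ) learner maintains a table
Q_MF(s, a) over all state–action pairs. On every trial the eligibility
traces are reset to zero; each visited pair's trace is incremented by 1
immediately before that stage's update, and all traces decay by λ after
each update. With the two-stage structure this reduces to: at the
second stage, the first-stage pair is updated with the prediction error
δ₁ = Q_MF(s₂, a₂) − Q_MF(s₁, a₁) (first-stage reward is always zero),
then the reward error δ₂ = r − Q_MF(s₂, a₂) updates the second-stage
pair fully and the first-stage pair scaled by λ. First-stage values are
kept separately per start state in two-start-state tasks; this is
exactly what prevents the model-free system from generalizing across
equivalent start states.

**Model-based system.** First-stage values are recomputed on every
trial by a one-step Bellman backup, Q_MB(s, a) = Σ_{s′} P(s′|s, a)
max_{a′} Q_MF(s′, a′). At the second stage the two systems coincide
(the SARSA rule is a delta rule for the immediate reward there), so
Q_MB = Q_MF at that level.

**Choice.** The first-stage policy is a softmax with inverse
temperature β over Q_net = w·Q_MB + (1−w)·Q_MF, plus π·rep(a) (bias
toward repeating the previous trial's stimulus choice) and ρ·resp(a)
(bias toward repeating the previous response key; key/stimulus
assignments are re-randomized every trial). The second stage uses
Q_MF alone, with no stickiness. Logits are clipped at ±30 so log choice
probabilities stay finite for arbitrarily large β.

**Transition beliefs.** Three modes:

- *known* — beliefs fixed at the veridical transition matrix. Used for
  all trade-off simulations.
- *one_shot* — uniform until the first observed transition from a start
  state, which reveals that state's full deterministic mapping (the
  other action must lead to the other state). Used when fitting the
  deterministic two-start tasks, mirroring how trained participants can
  infer the mapping from a single experience.
- *three_structure* — the agent entertains the flat structure and the
  two symmetric common/rare structures, tallies observed transitions,
  and adopts the maximum-likelihood structure (flat preferred on ties,
  so beliefs start uniform). The selection rule is not spelled out in
  the source literature; maximum likelihood with a flat tie-break is
  the simplest rule consistent with it.

Q values initialize at zero everywhere. For scalar tasks with negative
payoffs zero sits inside the payoff range, so no optimistic/pessimistic
bias is introduced. Ties in the second-stage max are taken by plain
argmax; under drifting schedules exact ties have probability zero.

## Tasks

All variants are two-stage MDPs built from five binary design factors
applied to the classic paradigm (binary rewards, drifting
probabilities with σ = 0.025 reflected at 0.25/0.75, one start state,
70/30 stochastic transitions, two second-stage choices, 201 trials):

1. broad_range — walk bounds widened to [0, 1]
2. fast_drift — walk σ raised to 0.2
3. deterministic_transitions — two equivalent start states,
   deterministic transitions
4. single_second_action — one forced second-stage response
5. scalar_payoff — the scheduled value is paid verbatim as points
   (the same numeric series as the probability version, so the two
   outcome kinds are expectation-matched)

Named presets cover the remaining variants: `dezfouli` (arms jump
between win probabilities 0.7 and 0.2, each reassigned uniformly with
probability 0.2 per trial), `doll` (two start states, deterministic,
original walks), `doll_stochastic_hybrid` (two start states with 70/30
transitions on broad/fast walks), `akam` (80/20 transitions, forced
second stage, 0.8/0.2 probabilities alternating in fixed 25-trial
blocks — the block length is not documented for the original design
and no result here depends on it), and the human-calibrated presets
`daw_human` (fixed initial probabilities 0.25/0.75 and 0.4/0.6, 125
trials) and `novel_human` (scalar payoffs on [−4, +5], σ = 2, one
schedule initialized in (−4, −1) and the other in (+1, +5), 125
trials).

Reflecting bounds fold overshoot by mirroring (v → 2·bound − v,
repeated while out of range). The fold is the quotient of the free
walk onto the interval, so schedules are generated as a cumulative
free walk followed by a single vectorized fold; mirroring (rather than
clipping) preserves the near-uniform stationary marginal, which is
what makes the mean pairwise arm difference one third of the range.

## Trade-off analysis

The accuracy–demand trade-off of a task is quantified as the
standardized slope (Pearson r) of reward rate on w across 11 w values
from 0 to 1. Within one replicate all w values — and all (β, α) grid
cells — share a single freshly drawn schedule, so the contrast
reflects w alone; replicates with zero outcome variance contribute
slope 0. Slopes are averaged over replicates for each cell of an
11-point β grid on [0, 10] × 11-point α grid on [0, 1] (λ fixed at
0.5; the task's surface is qualitatively unchanged at λ = 0 or 1,
which the test suite checks). The "learning rate up to 10" phrasing in
the source text is an evident slip — α is a rate in [0, 1] and all
published surfaces span learning rates up to 1 — so the α grid is
[0, 1].

The volume under a surface is the mean coefficient over cells with
β > 0 and α > 0, times the retained area (β_max × α_max): a β = 0
agent chooses at random and an α = 0 agent never learns, so their
slopes are pure noise. The factorial analysis builds this volume for
all 2⁵ = 32 factor combinations on identical grids.

The drift-rate sweep fixes (β, α) = (5, 0.5) — the median-fit regime
for the original task — and sweeps the walk σ over
{0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}. Effects are subtle (slopes of
order 0.01–0.03), so sweeps average at least several thousand
replicates per σ.

## Fitting

Per-session maximum a posteriori estimation: log likelihood of the
observed first-stage choices (plus second-stage choices where the task
affords a real choice; forced responses contribute nothing) with the
agent's learning rolled forward on the participant's actual choices
and outcomes, plus weak empirical priors — β ~ Gamma(4.82, 0.88)
(shape–scale; mean ≈ 4.2, consistent with fitted β medians of a few
units), π, ρ ~ Normal(0.15, 1.42) (sd), flat priors within bounds for
α, λ, w ∈ [0, 1] and β ∈ [0, 20]. Optimization is bounded L-BFGS-B
with objective tolerance 1e−6 and 25 random restarts by default
(initializations drawn from the priors where informative, uniformly in
bounds otherwise); the best restart wins, and the spread across
restarts is reported as an identifiability diagnostic. The Gamma prior
is −∞ at β = 0; the objective substitutes a large finite value there
so bounded quasi-Newton steps stay well defined.

Timed-out trials contribute no likelihood and no value update, and
clear the stickiness reference, but do not otherwise reset the agent.
Sessions with more than 20% timeouts are excluded (the human-data
criterion). BIC uses n = the number of modeled choice observations
(two per valid trial for tasks with a second-stage choice, one
otherwise); the source does not state its convention.

Model variants pin w at 0 (pure model-free) or 1 (pure model-based)
and toggle π and ρ. Fits to the scalar two-start task omit π by
default (its stimulus/key distinction collapses there and the
parsimonious model is preferred); fits to the classic task keep both.

Parameter recovery simulates agents with parameters drawn from the
same distributions the fitting machinery assumes — β from its Gamma
prior, stickiness from its Normal prior, α, λ, w uniform on [0, 1] —
runs each for the task's session length, refits by MAP, and reports
Pearson correlations between true and estimated values.

## Synthetic cohorts

No behavioral dataset is distributed with the task family, so seeded
synthetic cohorts stand in for human samples. Each subject receives an
independent schedule and session stream derived from one master seed
(regeneration is bit-identical). Parameter schemes: fixed, uniform in
bounds, or centered on the median fitted human parameters (classic
task: β=3.35, α=0.34, λ=0.65, π=0.21, ρ=0.05; scalar task: β=0.72,
α=0.67, λ=0.62, ρ=−0.06) with w drawn uniformly — the heterogeneity
the w–reward correlation analyses require. Timeouts are injected as an
i.i.d. Bernoulli flag that blanks the trial's choices.

What the cohorts do *not* emulate: reaction times, practice/training
phases, within-session drift in engagement, and any correlation
structure between parameters across subjects. Tests passing on these
cohorts demonstrate the pipeline's correctness and statistical power
under the model's own assumptions, not the fidelity of the model to
human behavior.

## Numerical and scale choices

The per-trial loops are compiled with numba; all randomness enters as
pre-drawn uniform variates from numpy `Generator` streams keyed by
`SeedSequence` tuples (master seed, replicate, …), so results are
independent of evaluation order and bit-reproducible. A pure-Python
twin of the session loop is held exactly equal to the compiled path by
the test suite, and the likelihood kernel is checked against an
independent replay through the scalar API.

Problem sizes: surfaces default to 1000 replicates (the scale of the
published analysis). The volume-ratio computation uses 6000 replicates
for the zero-factor task and 800 for the five-factor task: the
zero-factor volume is genuinely near zero (long-run estimate 0.0314
with Monte-Carlo s.e. 0.004 at 8000 replicates), so the denominator
dominates the ratio's error and gets the replicate budget. The
drift-rate sweep pairs replicates across σ by common random numbers and
uses 60,000 replicates per σ in the acceptance script: the σ = 0.1 vs
0.2 mean-slope gap is only ~0.005 against a per-replicate slope s.d. of
~0.36, so resolving the argmax needs tens of thousands of pairs. Recovery
uses 200 agents at 10 restarts; with this likelihood the extra
restarts beyond ~10 almost never change the optimum.

## Known limitations

- The Akam-style comparison with independently optimized parameters
  per agent is out of scope; only the fixed-grid methodology is
  implemented.
- `three_structure` belief selection is maximum likelihood, not a full
  posterior with structure priors; with a handful of observations the
  two differ only at exact ties.
- Stay-probability analyses binarize scalar payoffs at zero
  (win/loss framing); a median split would give different cell counts
  for strongly skewed schedules.
- No hierarchical (group-level) priors; each session is fitted
  independently.
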