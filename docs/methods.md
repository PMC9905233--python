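# Methods

This note documents the models implemented in cohesim, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## The bandit simulation

A multi-agent multi-armed bandit: *n* agents (default 6) choose among *k*
options (default 4) for *t*max iterations (default 30).  Option *a* pays
`payout_cent[a]` with probability `success_prob[a]`, independently per agent
and iteration.  Two option sets ship as constants: the simulation-study set
(20¢/80%, 10¢/90%, 20¢/45%, 20¢/20%) and the card/field-task set (30¢/80%,
10¢/90%, 30¢/30%, 10¢/20%).  Expected values over 30 rounds are derived as
`n_rounds · p · payout`, never stored.

Per iteration each agent draws *p* ~ U(0,1); if *p* < ε it explores (uniform
over all *k* options, so an exploration can coincide with the greedy
choice), otherwise it exploits the argmax of its value estimates.  The
boundary *p* = ε counts as exploitation; the event has probability zero and
only the classification flag, not the distribution of choices, depends on
the convention.

Choices within an iteration are simultaneous: all agents commit, payouts
are drawn independently per agent, then cohesion bonuses are computed from
the joint choice vector.  With *m* agents on the chosen option (including
the focal agent), the additive scheme pays `3 · (m−1)` cents and the
multiplicative scheme pays `payout · (m−1)` extra, so a lone chooser is
never inflated and a failed payout (0) stays 0.

Numerical choices, each a deliberate default:

* **Initial estimates are 0 for every option** — a neutral symmetric start;
  the forced-exploration phase (first 3 iterations, uniform choices) seeds
  real estimates before greedy play begins.
* **Update rule is the incremental sample average** — the standard
  stationary-bandit estimator; after any history, an option's estimate
  equals the arithmetic mean of all rewards received from it (tested to
  1e-9 against brute-force means of the logged rewards).
* **Bonuses are included in the update reward by default**
  (`bonus_in_update=True`): the point of the multiplicative scheme is that
  group-coupled rewards obfuscate feedback.  Setting it to `False` models
  separated feedback (bonus displayed apart from the option payout), the
  design used in the behavioral experiments.
* **Ties at the argmax break uniformly at random**, avoiding index bias in
  early iterations when many estimates are exactly equal.
* **Reproducibility**: one master seed; each run draws from its own
  `SeedSequence` substream, so identical configs reproduce byte-identical
  record streams and runs are independent.

## The Poisson mixed model of the simulation output

`fit_profitable_count_model` fits counts of agents on the profitable option
per run × iteration: `count ~ iteration * bonus_kind + (1 | run)`, Poisson
with log link.  Bonus kind enters through sum-to-zero (deviation) contrasts
in the fixed order (none, additive, multiplicative), so each kind's
coefficient reads "versus the mean of all kinds"; the omitted level's
coefficient is derived as the negative sum of the coded ones with a
delta-method CI.  Coefficient values depend on this coding, which is why it
is fixed and documented.  The random intercept is grouped by the `run`
column exactly as logged — runs are numbered within scheme, mirroring how
simulation output tables are laid out.

With the default study conditions the model yields an iteration effect of
≈ +0.02 with a positive no-bonus interaction and a negative multiplicative
interaction (the most negative of the three), and the pooled late-round
(iterations 16–30) profitable share orders none > additive >
multiplicative.  The acceptance suite asserts exactly these properties.

## The GLMM engine

No maximum-likelihood Poisson/logistic mixed-model routine with the needed
random-effects structures was available in the Python stack, so
`cohesim.glmm` implements the classic Laplace scheme used by mixed-model
software across languages:

1. For fixed variance parameters θ (one SD per independent random-effect
   term), the joint penalized mode of (β, u) is found by Newton/IRLS steps;
   the random-effects block is solved sparsely (`scipy.sparse` LU) with a
   Schur complement for the dense fixed-effects block.
2. The Laplace-approximate marginal log-likelihood
   `ll(û) − ûᵀΛ⁻¹û/2 − log|Λ|/2 − log|ZᵀWZ + Λ⁻¹|/2`
   is maximized over log θ (Nelder–Mead), followed by a polish stage that
   moves β into the outer optimization — the criterion glmer-style
   estimators maximize.

Fixed-effect covariances are the Schur complement of the random-effects
block of the joint negative Hessian at the optimum, i.e. conditional on θ̂
(mixed-model software convention); CIs and p-values are Wald.  Random-effect
terms are independent (no intercept–slope correlation), covering random
intercepts and uncorrelated random slopes.  The test suite cross-checks the
engine against `lme4::glmer` on shared data (coefficients, variance
component and log-likelihood agree to ≈ 1e-3) and against a Poisson GEE for
the marginal-slope identity of log-link random-intercept models.

Pseudo-R² values follow the variance-decomposition (marginal/conditional)
definition with π²/3 as the logistic observation-level variance and the
lognormal approximation `ln(1 + 1/λ̄)` for Poisson; random-slope terms
contribute `σ² · E[x²]`.  These are descriptive summaries, not test
statistics.

## Behavioral metrics

**Choice score**: 3 points per profitable round, 2 per neutral, 1 per
unprofitable, 0 per missed round, summed over the game (bounds 0 and
3·n_rounds are asserted as invariants).

**Half-change round**: a change occurs in round *t* when the option chosen
in *t* differs from the most recent *actual* prior choice — missed rounds
neither count as changes nor break streaks.  The statistic is the smallest
*t* whose cumulative change count reaches ⌈total/2⌉.  A player with zero
changes gets round 1 (immediate exploitation); `n_changes` is reported
alongside so analyses can exclude such players.

**L-F score**: every player starts each round at 0.  For each move by mover
*m* and each other player *o*, the change in their pairwise distance decides
the increments: away → (*m* +1, *o* −1), closer → (*m* −1, *o* +1),
unchanged → nothing.  Increments are applied **per (mover, other) pair**:
in the canonical two-move scenario (A steps away from B and C; then B steps
toward A and away from C) the pairwise rule gives A +2 for the first move,
whereas a per-move reading would give +1.  Only the pairwise rule makes the
second move's arithmetic balance (B: −1 + 1 = 0) and makes increments
zero-sum across players — a conservation property the suite asserts on
arbitrary trajectories — so the mover's first-move credit is +2 here, and
the non-movers' −1 each is unambiguous.  Overall scores are per-round scores
summed over rounds.

**Field distribution**: game level — % of board cells occupied by anyone at
any time; move level — mean over snapshots (initial placement plus one per
move) of the % of cells currently occupied.  Both normalize by board size;
the board is a regular hexagon of configurable radius (default 5 → 91
cells), since the original playing field's exact cell count is not fixed by
the task description.

**Transitivity**: players form a complete weighted graph, weight
`1/(1 + d)` with `d` the hex distance in fields; `1/max(d,1)` is available
as a config knob for the inverse-distance reading.  The global coefficient
is the Onnela geometric-mean triangle intensity averaged over nodes (as in
networkx), which equals 1 whenever all pairwise distances are equal — in
particular for a fully stacked group.  Weighted "global clustering" is
underdetermined as a phrase; the variant is configurable and this default is
asserted against a brute-force O(n³) triangle enumeration.

Axial coordinates with (0,0) at the centre; rounds and event indices are
1-based; all money is integer cents end-to-end.

## Synthetic generators

The generators produce *recoverable structure*, not human realism.

**Card sessions**: each agent holds a current option (starting at its goal)
and switches at scheduled rounds or with per-round probability ε, always to
a uniformly different option; realized switch rounds are stored as ground
truth.  Agents do not learn — value learning lives in the bandit simulator;
here the point is that the half-change round and choice score can be
checked against construction.  Payouts are per-agent Bernoulli draws;
the additive bonus pays 3·(m−1).

**Movement sessions**: agents start on the six distinct cells of the
central ring and keep their positions across rounds.  Per round, each agent
may take up to `moves_per_round` (default 10) single-cell steps; the mover
is sampled with probability ∝ `leader_bias + 0.25`, so high-bias agents
move first and most.  Each step greedily reduces Euclidean distance to a
target that interpolates between the agent's goal reward field and the
current group centroid with weight `cohesion_weight`
(`(goal + w·centroid) / (1 + w)`); an agent whose best step no longer
improves settles for the round.  Reward fields sit on four alternating
board corners; the option scored for a round is the field occupied at round
end (none → no payout).  Rounds end on the move cap rather than a wall
clock.  This minimal rule yields the two signals the tests need — a
designated leader tops the L-F ranking in ≈100/100 seeded sessions, and
cohesion weight monotonically shrinks the field distribution — but it does
not emulate human exploration strategies, communication through movement,
or speed differences, so passing tests certify the metrics and pipeline,
not conclusions about human behaviour.

Designated-leader ground truth uses a fixed threshold (`leader_bias ≥ 1`).

## Analysis pipeline

**Learning curve** (`fit_learning_curve`): logistic mixed model of the
binary profitable-choice indicator.  Without a condition the fixed part is
`-1 + round` (no intercept, as the curve is anchored at chance through the
random effects); with a condition it is `condition * round` with intercept.
The random-effects structure is configurable; the default is random
intercepts for participant and group plus an uncorrelated per-participant
random slope for round, a middle reading of "round, participant and group
as random effects".

**Exploration–quality** (`fit_exploration_quality`): ML linear mixed models
`choice_score ~ hcr + hcr²` and the linear-only reduction, both with a group
random intercept (dropped with a warning below two groups), compared by a
1-df likelihood-ratio χ².  Delegated to statsmodels MixedLM.

**Mediation** (`mediate`): product of coefficients with OLS paths — total
from `y ~ x`, a-path from `m ~ x`, b-path and direct from `y ~ x + m`,
indirect = a·b — and percentile bootstrap CIs (≥ 100 resamples enforced,
1,000 by default).  For linear models total = direct + indirect exactly
(asserted to 1e-8).  The proportion mediated is reported as 0 whenever the
indirect CI spans zero, matching the null-mediation reporting convention;
binary outcomes are handled on the linear-probability scale, an
approximation noted here deliberately.

**Group comparisons** (`compare_groups`): Welch t with Cohen's d, rank-sum
with continuity correction and rank-biserial effect size, χ² with Cramér's
V — thin wrappers over scipy.

## Problem sizes and determinism

The acceptance suite runs the full simulation experiment (3 schemes ×
1,000 runs × 30 iterations × 6 agents, ≈ 15 s including the mixed-model
fit) and 100-replicate recovery studies for each pipeline stage; recovery
replicates use moderate designs (e.g. 3 × 40 runs × 12 iterations for the
count model, 6 groups × 6 players × 30 rounds for the learning curve) —
large enough for calibrated coverage, small enough to keep each fit around
a second.  All stochastic stages are seeded; fits are deterministic given
their input.

## Known limitations

* The GLMM engine covers Poisson and Bernoulli-logit families with
  independent Gaussian random-effect terms; correlated intercept–slope
  blocks and other families are out of scope (statsmodels MixedLM covers
  the Gaussian case).
* Laplace (nAGQ = 1) accuracy degrades for binary outcomes with very few
  observations per group; the designs used here have ≥ 15.
* The movement generator's leadership signal is by construction
  (move-order bias plus centroid-chasing); it cannot distinguish the
  alternative leadership operationalizations (first-mover classification,
  network centrality) that a richer behavioural model would support.
* Percentages in the spatial metrics depend on the configured board radius;
  compare sessions only at equal board size.
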