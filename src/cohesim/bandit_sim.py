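"""Multi-agent multi-armed-bandit simulator with epsilon-greedy agents.

Six agents repeatedly choose among four reward options with unknown Bernoulli
payout distributions.  Each agent keeps a sample-average estimate of every
option's value and, per iteration, explores a uniformly random option with
probability ``epsilon`` or exploits the current argmax of its estimates.  All
agents commit their choices simultaneously; a group-cohesion bonus can then be
paid depending on how many agents co-chose the same option:

``none``
    no bonus;
``additive``
    a fixed amount (default 3 cents) for each *other* co-chooser;
``multiplicative``
    the drawn payout is multiplied by the number of co-choosers, so the bonus
    increment is ``payout * (m - 1)``.

The multiplicative scheme couples an option's effective reward to the other
agents' behaviour, which makes the reward distribution non-stationary and
corrupts value estimates — the mechanism this simulator exists to expose.  By
default the bonus is folded into the reward used for estimate updates
(``bonus_in_update=True``); setting it to ``False`` models separated feedback,
where agents learn from the raw option payout only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError

__all__ = [
    "OptionSpec",
    "BonusScheme",
    "SimConfig",
    "AgentState",
    "IterationRecord",
    "SIMULATION_OPTIONS",
    "EXPERIMENT_OPTIONS",
    "OPTION_ROLES",
    "profitable_option",
    "epsilon_greedy_choose",
    "compute_bonus",
    "update_estimate",
    "run_simulation",
    "records_to_frame",
    "counts_to_frame",
    "summarize_choice_frequencies",
]


@dataclass(frozen=True)
class OptionSpec:
    """One reward option: a payout in cents won with a fixed probability."""

    option_id: int
    payout_cent: int
    success_prob: float
    name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.success_prob <= 1.0:
            raise ConfigError(
                f"success_prob must be in [0, 1], got {self.success_prob} "
                f"for option {self.option_id}"
            )
        if self.payout_cent < 0:
            raise ConfigError(
                f"payout_cent must be >= 0, got {self.payout_cent} "
                f"for option {self.option_id}"
            )

    def expected_successes(self, n_rounds: int) -> float:
        """Expected number of successful draws over ``n_rounds`` choices."""
        return n_rounds * self.success_prob

    def expected_value(self, n_rounds: int) -> float:
        """Expected total payout in cents over ``n_rounds`` choices."""
        return n_rounds * self.success_prob * self.payout_cent


#: Options of the original movement experiment / the simulation study:
#: profitable 20c/80%, secure neutral 10c/90%, risky neutral 20c/45%,
#: unprofitable 20c/20% (expected totals over 30 rounds: 480/270/270/120c).
SIMULATION_OPTIONS: tuple[OptionSpec, ...] = (
    OptionSpec(0, 20, 0.80, "profitable"),
    OptionSpec(1, 10, 0.90, "secure neutral"),
    OptionSpec(2, 20, 0.45, "risky neutral"),
    OptionSpec(3, 20, 0.20, "unprofitable"),
)

#: Options of the card-choice and movement experiments: profitable 30c/80%,
#: secure neutral 10c/90%, risky neutral 30c/30%, unprofitable 10c/20%
#: (expected totals over 30 rounds: 720/270/270/60c).
EXPERIMENT_OPTIONS: tuple[OptionSpec, ...] = (
    OptionSpec(0, 30, 0.80, "profitable"),
    OptionSpec(1, 10, 0.90, "secure neutral"),
    OptionSpec(2, 30, 0.30, "risky neutral"),
    OptionSpec(3, 10, 0.20, "unprofitable"),
)

#: Scoring roles shared by both option sets (by option_id).
OPTION_ROLES: Mapping[int, str] = {
    0: "profitable",
    1: "neutral",
    2: "neutral",
    3: "unprofitable",
}


def profitable_option(options: Sequence[OptionSpec]) -> int:
    """option_id with the highest per-round expected value."""
    if not options:
        raise EmptyInputError("empty option set")
    best = max(options, key=lambda o: o.success_prob * o.payout_cent)
    return best.option_id


@dataclass(frozen=True)
class BonusScheme:
    """Group-cohesion bonus paid for co-choosing an option."""

    kind: str = "none"  # none | additive | multiplicative
    additive_amount_cent: int = 3

    def __post_init__(self):
        if self.kind not in ("none", "additive", "multiplicative"):
            raise ConfigError(f"bonus kind must be none/additive/multiplicative, got {self.kind!r}")
        if self.additive_amount_cent < 0:
            raise ConfigError(f"additive_amount_cent must be >= 0, got {self.additive_amount_cent}")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulation experiment.

    Defaults reproduce the simulation-study conditions: 6 agents, the four
    simulation-study options, epsilon 0.1, 30 iterations with the first 3 forced to
    uniform exploration, 1,000 independent runs.
    """

    n_agents: int = 6
    options: tuple[OptionSpec, ...] = SIMULATION_OPTIONS
    epsilon: float = 0.1
    n_iterations: int = 30
    forced_exploration_iterations: int = 3
    n_runs: int = 1000
    bonus: BonusScheme = field(default_factory=BonusScheme)
    seed: int = 0
    bonus_in_update: bool = True

    def __post_init__(self):
        if self.n_agents < 1:
            raise ConfigError(f"n_agents must be >= 1, got {self.n_agents}")
        if len(self.options) < 2:
            raise ConfigError(f"options must list >= 2 options, got {len(self.options)}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.n_iterations < 1:
            raise ConfigError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0 <= self.forced_exploration_iterations <= self.n_iterations:
            raise ConfigError(
                "forced_exploration_iterations must be in [0, n_iterations], got "
                f"{self.forced_exploration_iterations}"
            )
        if self.n_runs < 1:
            raise ConfigError(f"n_runs must be >= 1, got {self.n_runs}")
        ids = [o.option_id for o in self.options]
        if ids != list(range(len(ids))):
            raise ConfigError(f"options must have option_id 0..k-1 in order, got {ids}")


@dataclass
class AgentState:
    """Per-agent knowledge: sample-average value estimate and count per option.

    Estimates start at zero for every option, i.e. all options are assumed
    equally profitable until tried.
    """

    value_estimates: np.ndarray
    choice_counts: np.ndarray

    @classmethod
    def initial(cls, n_options: int, initial_value: float = 0.0) -> "AgentState":
        if n_options < 1:
            raise ConfigError("AgentState needs at least one option")
        return cls(
            value_estimates=np.full(n_options, float(initial_value)),
            choice_counts=np.zeros(n_options, dtype=np.int64),
        )

    @property
    def n_options(self) -> int:
        return len(self.value_estimates)


@dataclass(frozen=True)
class IterationRecord:
    """Joint outcome of one iteration of one run."""

    run: int
    iteration: int  # 1-based
    choices: tuple[int, ...]  # per agent
    payouts: tuple[int, ...]  # per agent, cents, excluding bonus
    bonuses: tuple[int, ...]  # per agent, cents
    counts: tuple[int, ...]  # per option, number of agents choosing it


def epsilon_greedy_choose(
    state: AgentState,
    epsilon: float,
    rng: np.random.Generator,
    return_exploration: bool = False,
):
    """Choose an option: explore uniformly with probability ``epsilon``,
    otherwise exploit the argmax of the value estimates (ties broken uniformly
    at random).

    A draw ``p`` from U(0, 1) with ``p < epsilon`` counts as exploration; the
    boundary ``p == epsilon`` exploits (a measure-zero convention).  With
    ``return_exploration=True`` the classification of the draw is returned
    alongside the option id.
    """
    k = state.n_options
    if k < 2:
        raise ConfigError(f"epsilon-greedy needs >= 2 options, got {k}")
    if not 0.0 <= epsilon <= 1.0:
        raise ConfigError(f"epsilon must be in [0, 1], got {epsilon}")
    explored = bool(rng.random() < epsilon)
    if explored:
        choice = int(rng.integers(k))
    else:
        est = state.value_estimates
        maxima = np.flatnonzero(est == est.max())
        choice = int(maxima[0]) if len(maxima) == 1 else int(rng.choice(maxima))
    if return_exploration:
        return choice, explored
    return choice


def compute_bonus(
    counts: Sequence[int] | np.ndarray,
    chosen: int,
    payout: int,
    scheme: BonusScheme,
) -> int:
    """Cohesion-bonus increment (cents) for an agent that chose ``chosen``.

    ``counts[chosen]`` is the number of agents on that option *including* the
    focal agent, so a lone chooser (m = 1) earns no bonus under any scheme.
    Under the multiplicative scheme the agent receives ``payout * m`` in total,
    of which ``payout * (m - 1)`` is the bonus increment returned here.
    """
    m = int(counts[chosen])
    if m < 1:
        raise ValueError(
            f"counts[{chosen}] = {m}: the focal agent must be counted among the choosers"
        )
    if scheme.kind == "none":
        return 0
    if scheme.kind == "additive":
        return scheme.additive_amount_cent * (m - 1)
    return int(payout) * m - int(payout)


def update_estimate(state: AgentState, option: int, reward: float) -> AgentState:
    """Fold one observed reward into the sample-average estimate of ``option``.

    Incremental form of the arithmetic mean of all rewards received from that
    option; the state is updated in place and returned.
    """
    if not 0 <= option < state.n_options:
        raise ValueError(f"option {option} out of range 0..{state.n_options - 1}")
    state.choice_counts[option] += 1
    n = state.choice_counts[option]
    est = state.value_estimates[option]
    state.value_estimates[option] = est + (reward - est) / n
    return state


def run_simulation(config: SimConfig) -> list[IterationRecord]:
    """Run ``config.n_runs`` independent runs of the joint-choice simulation.

    Per iteration all agents commit a choice (uniform-random during the forced
    exploration phase, epsilon-greedy afterwards), payouts are drawn
    independently per agent from the chosen option's Bernoulli distribution,
    and bonuses are computed from the joint choice vector.  Each run draws
    from its own deterministic substream of ``config.seed``, so a given
    (config, seed) pair reproduces the identical record sequence.
    """
    k = len(config.options)
    payout_arr = np.array([o.payout_cent for o in config.options], dtype=np.int64)
    prob_arr = np.array([o.success_prob for o in config.options])
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    records: list[IterationRecord] = []
    for run_idx in range(config.n_runs):
        rng = np.random.default_rng(children[run_idx])
        states = [AgentState.initial(k) for _ in range(config.n_agents)]
        for t in range(1, config.n_iterations + 1):
            if t <= config.forced_exploration_iterations:
                choices = [int(rng.integers(k)) for _ in range(config.n_agents)]
            else:
                choices = [
                    epsilon_greedy_choose(s, config.epsilon, rng) for s in states
                ]
            choice_arr = np.asarray(choices)
            success = rng.random(config.n_agents) < prob_arr[choice_arr]
            payouts = np.where(success, payout_arr[choice_arr], 0)
            counts = np.bincount(choice_arr, minlength=k)
            bonuses = [
                compute_bonus(counts, c, int(p), config.bonus)
                for c, p in zip(choices, payouts)
            ]
            for agent, (state, c) in enumerate(zip(states, choices)):
                reward = float(payouts[agent])
                if config.bonus_in_update:
                    reward += bonuses[agent]
                update_estimate(state, c, reward)
            records.append(
                IterationRecord(
                    run=run_idx,
                    iteration=t,
                    choices=tuple(int(c) for c in choices),
                    payouts=tuple(int(p) for p in payouts),
                    bonuses=tuple(int(b) for b in bonuses),
                    counts=tuple(int(c) for c in counts),
                )
            )
    return records


def records_to_frame(records: Iterable[IterationRecord]) -> pd.DataFrame:
    """Long per-agent table: run, iteration, agent, choice, payout_cent, bonus_cent."""
    rows = []
    for rec in records:
        for agent, (c, p, b) in enumerate(zip(rec.choices, rec.payouts, rec.bonuses)):
            rows.append((rec.run, rec.iteration, agent, c, p, b))
    if not rows:
        raise EmptyInputError("no iteration records")
    return pd.DataFrame(
        rows, columns=["run", "iteration", "agent", "choice", "payout_cent", "bonus_cent"]
    )


def counts_to_frame(records: Iterable[IterationRecord]) -> pd.DataFrame:
    """Per-iteration option counts: run, iteration, option, count."""
    rows = []
    for rec in records:
        for opt, n in enumerate(rec.counts):
            rows.append((rec.run, rec.iteration, opt, n))
    if not rows:
        raise EmptyInputError("no iteration records")
    return pd.DataFrame(rows, columns=["run", "iteration", "option", "count"])


def summarize_choice_frequencies(
    records: Sequence[IterationRecord] | Mapping[str, Sequence[IterationRecord]],
    label: str = "all",
) -> pd.DataFrame:
    """Percent of agent-iteration choices falling on each option.

    Accepts either one record sequence (labelled ``label``) or a mapping of
    label -> record sequence; returns a table with columns
    ``label, option, percent`` whose percentages sum to 100 per label.
    """
    if isinstance(records, Mapping):
        parts = [summarize_choice_frequencies(v, label=k) for k, v in records.items()]
        if not parts:
            raise EmptyInputError("no records to summarize")
        return pd.concat(parts, ignore_index=True)
    records = list(records)
    if not records:
        raise EmptyInputError("no records to summarize")
    k = len(records[0].counts)
    totals = np.zeros(k, dtype=np.int64)
    for rec in records:
        totals += np.asarray(rec.counts)
    pct = 100.0 * totals / totals.sum()
    return pd.DataFrame({"label": label, "option": np.arange(k), "percent": pct})
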