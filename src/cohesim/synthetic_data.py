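"""Synthetic card-choice and hex-board movement sessions with ground truth.

Real sessions of the two experiment types (a repeated card-choice game and a
movement game on a hexagonal board with four reward fields) cannot ship with
the package, so every metric and model is exercised on generated sessions
whose exploration, leadership and cohesion structure is known exactly.

Card sessions: six agents each hold a current option (their ``goal_option``)
and switch options either at explicitly scheduled rounds or at random with
per-round probability ``epsilon`` — an exploration process whose switch
rounds are recorded as ground truth, so the half-change round and choice
score can be checked against construction.  Payouts are Bernoulli draws of
the option's payout; the additive cohesion bonus pays 3 cents per co-chooser.

Movement sessions: agents take single-cell steps toward a target that
interpolates between their goal reward field and the current group centroid
with weight ``cohesion_weight`` (0 = purely goal-driven, large = huddling).
Move order is sampled with probability proportional to ``leader_bias``, so
high-bias agents move first and drag the centroid — and with it the
followers — behind them, creating a recoverable leadership signal for the
L-F score.  The rule is deliberately minimal: it creates graded, recoverable
cohesion and leadership, not a model of human strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bandit_sim import BonusScheme, OptionSpec, EXPERIMENT_OPTIONS, compute_bonus
from .behavior_metrics import MoveEvent, RoundChoice, validate_trajectory
from .errors import ConfigError
from .hexgrid import HexBoard, HexCell, axial_to_xy, hex_distance

__all__ = [
    "AgentProfile",
    "WorldConfig",
    "Session",
    "LEADER_BIAS_THRESHOLD",
    "default_reward_cells",
    "generate_card_session",
    "generate_honeycomb_session",
    "ground_truth_labels",
]

#: leader_bias at or above this marks the profile as a designated leader.
LEADER_BIAS_THRESHOLD = 1.0


@dataclass(frozen=True)
class AgentProfile:
    """Behavioral parameters of one synthetic agent."""

    epsilon: float = 0.1
    switch_schedule: tuple[int, ...] | None = None
    cohesion_weight: float = 0.0
    leader_bias: float = 0.0
    goal_option: int = 0

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not math.isfinite(self.cohesion_weight) or self.cohesion_weight < 0:
            raise ConfigError(f"cohesion_weight must be finite and >= 0, got {self.cohesion_weight}")
        if not math.isfinite(self.leader_bias) or self.leader_bias < 0:
            raise ConfigError(f"leader_bias must be finite and >= 0, got {self.leader_bias}")


def default_reward_cells(board: HexBoard) -> tuple[HexCell, ...]:
    """Four well-separated reward-field cells: alternating board corners."""
    c = board.corners()
    return (c[0], c[1], c[3], c[4])


@dataclass(frozen=True)
class WorldConfig:
    """Movement-session world: board, reward-field placement, round structure."""

    board_radius: int = 5
    options: tuple[OptionSpec, ...] = EXPERIMENT_OPTIONS
    reward_cells: tuple[HexCell, ...] | None = None  # None -> default_reward_cells
    n_rounds: int = 30
    moves_per_round: int = 10
    bonus: BonusScheme = field(default_factory=BonusScheme)
    seed: int = 0

    def __post_init__(self):
        board = HexBoard(self.board_radius)
        cells = self.resolved_reward_cells()
        if len(cells) != len(self.options):
            raise ConfigError(
                f"reward_cells: expected {len(self.options)} cells, got {len(cells)}"
            )
        if len(set(cells)) != len(cells):
            raise ConfigError("reward_cells must be distinct")
        for cell in cells:
            if not board.contains(cell):
                raise ConfigError(f"reward cell {tuple(cell)} is off the board")
        if self.n_rounds < 1:
            raise ConfigError(f"n_rounds must be >= 1, got {self.n_rounds}")
        if self.moves_per_round < 1:
            raise ConfigError(f"moves_per_round must be >= 1, got {self.moves_per_round}")

    def resolved_reward_cells(self) -> tuple[HexCell, ...]:
        if self.reward_cells is not None:
            return tuple(HexCell(*c) for c in self.reward_cells)
        return default_reward_cells(HexBoard(self.board_radius))


@dataclass
class Session:
    """One generated session plus its generation-time ground truth."""

    kind: str  # "card" | "honeycomb"
    players: list[str]
    choices: list[RoundChoice]
    moves: list[MoveEvent] = field(default_factory=list)
    initial_positions: dict[str, HexCell] = field(default_factory=dict)
    options: tuple[OptionSpec, ...] = EXPERIMENT_OPTIONS
    truth: dict = field(default_factory=dict)

    def choices_by_player(self) -> dict[str, list[RoundChoice]]:
        out: dict[str, list[RoundChoice]] = {p: [] for p in self.players}
        for c in self.choices:
            out[c.player].append(c)
        return out


def _player_names(n: int) -> list[str]:
    return [f"p{i + 1}" for i in range(n)]


def _draw_payout(option: OptionSpec, rng: np.random.Generator) -> int:
    return option.payout_cent if rng.random() < option.success_prob else 0


def _round_choices(
    round_no: int,
    players: Sequence[str],
    chosen: Sequence[int | None],
    options: Sequence[OptionSpec],
    bonus: BonusScheme,
    rng: np.random.Generator,
) -> list[RoundChoice]:
    """Draw payouts and bonuses for one round of joint choices."""
    k = len(options)
    counts = np.zeros(k, dtype=int)
    for c in chosen:
        if c is not None:
            counts[c] += 1
    out = []
    for player, c in zip(players, chosen):
        if c is None:
            out.append(RoundChoice(round_no, player, None, 0, 0))
            continue
        payout = _draw_payout(options[c], rng)
        b = compute_bonus(counts, c, payout, bonus)
        out.append(RoundChoice(round_no, player, int(c), payout, int(b)))
    return out


def generate_card_session(
    profiles: Sequence[AgentProfile],
    options: Sequence[OptionSpec] = EXPERIMENT_OPTIONS,
    bonus: BonusScheme = BonusScheme(),
    seed: int = 0,
    n_rounds: int = 30,
) -> Session:
    """Generate one card-choice session (default: 6 players, 30 rounds,
    the card-task option set, additive 3-cent bonus available via ``bonus``).

    Each agent starts on its ``goal_option`` and changes option at its
    scheduled rounds (``switch_schedule``) or, absent a schedule, with
    per-round probability ``epsilon``; a change always picks a different
    option uniformly.  The realized switch rounds per player are stored as
    ground truth.
    """
    k = len(options)
    if k < 2:
        raise ConfigError(f"need >= 2 options, got {k}")
    for i, p in enumerate(profiles):
        if not 0 <= p.goal_option < k:
            raise ConfigError(f"profile {i}: goal_option {p.goal_option} out of range")
        if p.switch_schedule is not None:
            bad = [r for r in p.switch_schedule if not 2 <= r <= n_rounds]
            if bad:
                raise ConfigError(f"profile {i}: switch rounds {bad} outside 2..{n_rounds}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    players = _player_names(len(profiles))
    current = [p.goal_option for p in profiles]
    switch_rounds: dict[str, list[int]] = {p: [] for p in players}
    choices: list[RoundChoice] = []
    for t in range(1, n_rounds + 1):
        for i, prof in enumerate(profiles):
            if prof.switch_schedule is not None:
                do_switch = t in prof.switch_schedule
            else:
                do_switch = t > 1 and rng.random() < prof.epsilon
            if do_switch:
                alternatives = [o for o in range(k) if o != current[i]]
                current[i] = int(rng.choice(alternatives))
                switch_rounds[players[i]].append(t)
        choices.extend(
            _round_choices(t, players, list(current), options, bonus, rng)
        )
    truth = {
        "generator": "cohesim.card",
        "seed": seed,
        "bonus_kind": bonus.kind,
        "per_player": {
            p: {
                "switch_rounds": tuple(switch_rounds[p]),
                "epsilon": prof.epsilon,
                "goal_option": prof.goal_option,
                "cohesion_weight": prof.cohesion_weight,
                "leader": prof.leader_bias >= LEADER_BIAS_THRESHOLD,
            }
            for p, prof in zip(players, profiles)
        },
    }
    return Session(
        kind="card", players=players, choices=choices,
        options=tuple(options), truth=truth,
    )


def generate_honeycomb_session(
    profiles: Sequence[AgentProfile],
    world: WorldConfig = WorldConfig(),
) -> Session:
    """Generate one movement session on the hexagonal board.

    Per round, agents alternate single-cell steps (mover sampled with
    probability proportional to ``leader_bias``, so high-bias agents move
    first and most) toward a per-agent target interpolating between the
    agent's goal reward field and the current group centroid with weight
    ``cohesion_weight``.  An agent whose best step no longer reduces the
    distance to its target settles for the round; a round ends when everyone
    settled or exhausted the per-round move cap.  The option scored for a
    round is the reward field the agent occupies at round end (none
    otherwise, with no payout).
    """
    board = HexBoard(world.board_radius)
    reward_cells = world.resolved_reward_cells()
    cell_option = {cell: opt.option_id for cell, opt in zip(reward_cells, world.options)}
    k = len(world.options)
    for i, p in enumerate(profiles):
        if not 0 <= p.goal_option < k:
            raise ConfigError(f"profile {i}: goal_option {p.goal_option} out of range")
    rng = np.random.default_rng(np.random.SeedSequence(world.seed))
    players = _player_names(len(profiles))
    ring = board.ring(1)
    if len(profiles) > len(ring):
        raise ConfigError(
            f"at most {len(ring)} agents fit on the central start ring, got {len(profiles)}"
        )
    initial = {p: ring[i] for i, p in enumerate(players)}
    pos = dict(initial)
    goal_xy = {
        p: axial_to_xy(reward_cells[prof.goal_option])
        for p, prof in zip(players, profiles)
    }
    weights = np.array([prof.leader_bias + 0.25 for prof in profiles])

    moves: list[MoveEvent] = []
    choices: list[RoundChoice] = []
    for t in range(1, world.n_rounds + 1):
        remaining = {p: world.moves_per_round for p in players}
        settled = {p: False for p in players}
        event_index = 0
        while True:
            active = [
                i for i, p in enumerate(players)
                if remaining[p] > 0 and not settled[p]
            ]
            if not active:
                break
            w = weights[active]
            mover_i = int(rng.choice(active, p=w / w.sum()))
            mover = players[mover_i]
            prof = profiles[mover_i]
            cx = float(np.mean([axial_to_xy(c)[0] for c in pos.values()]))
            cy = float(np.mean([axial_to_xy(c)[1] for c in pos.values()]))
            gx, gy = goal_xy[mover]
            w_c = prof.cohesion_weight
            tx = (gx + w_c * cx) / (1.0 + w_c)
            ty = (gy + w_c * cy) / (1.0 + w_c)
            here = pos[mover]
            hx, hy = axial_to_xy(here)
            d_here = math.hypot(hx - tx, hy - ty)
            best_cells, best_d = [], d_here - 1e-9
            for nb in board.neighbors(here):
                nx, ny = axial_to_xy(nb)
                d = math.hypot(nx - tx, ny - ty)
                if d < best_d - 1e-12:
                    best_cells, best_d = [nb], d
                elif best_cells and abs(d - best_d) <= 1e-12:
                    best_cells.append(nb)
            if not best_cells:
                settled[mover] = True
                continue
            target = best_cells[0] if len(best_cells) == 1 else best_cells[int(rng.integers(len(best_cells)))]
            event_index += 1
            moves.append(MoveEvent(t, event_index, mover, here, target))
            pos[mover] = target
            remaining[mover] -= 1
        chosen = [cell_option.get(pos[p]) for p in players]
        choices.extend(
            _round_choices(t, players, chosen, world.options, world.bonus, rng)
        )
    validate_trajectory(moves, initial, board)
    truth = {
        "generator": "cohesim.honeycomb",
        "seed": world.seed,
        "bonus_kind": world.bonus.kind,
        "board_radius": world.board_radius,
        "per_player": {
            p: {
                "goal_option": prof.goal_option,
                "cohesion_weight": prof.cohesion_weight,
                "leader_bias": prof.leader_bias,
                "leader": prof.leader_bias >= LEADER_BIAS_THRESHOLD,
                "switch_rounds": (),
            }
            for p, prof in zip(players, profiles)
        },
    }
    return Session(
        kind="honeycomb", players=players, choices=choices, moves=moves,
        initial_positions=initial, options=tuple(world.options), truth=truth,
    )


def ground_truth_labels(session: Session) -> dict:
    """Per-player and per-group ground-truth labels of a generated session.

    Raises ``ValueError`` for logs not produced by this module (no embedded
    generation record).
    """
    if not isinstance(session, Session) or not session.truth.get("generator", "").startswith("cohesim."):
        raise ValueError("session was not generated by cohesim.synthetic_data")
    per_player = session.truth["per_player"]
    return {
        "group": {
            "kind": session.kind,
            "seed": session.truth["seed"],
            "bonus_kind": session.truth["bonus_kind"],
            "n_leaders": sum(1 for v in per_player.values() if v["leader"]),
        },
        "players": {
            p: dict(labels) for p, labels in per_player.items()
        },
    }
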