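"""Behavioral statistics for group decision making and movement sessions.

Per player:

* **choice score** — decision quality summed over rounds (profitable option
  3 points, neutral 2, unprofitable 1, missed round 0);
* **half-change round** — the earliest round by which at least half of all the
  player's option changes had occurred; operationalizes the length of the
  exploration phase;
* **L-F score** — leadership/followership accumulated from per-move pairwise
  distance changes: a mover gains a point against every other player it moves
  away from (it "leads away" / is followed) and loses one against every player
  it moves toward, with the signs mirrored on the other player.  Increments
  are zero-sum per move by construction.

Per group (on hexagonal-board trajectories):

* **field distribution** — percent of board cells ever occupied (game level)
  and the mean percent occupied per move snapshot (move level); lower values
  mean a spatially tighter group;
* **transitivity** — the global weighted clustering coefficient of the
  complete player-proximity graph with edge weights ``1 / (1 + distance)``;
  1 when all players are mutually equidistant (in particular when stacked on
  one cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyInputError, TrajectoryError
from .hexgrid import HexBoard, HexCell, hex_distance

__all__ = [
    "MoveEvent",
    "RoundChoice",
    "PlayerScores",
    "GroupCohesion",
    "choice_score",
    "half_change_round",
    "player_scores",
    "lf_increments",
    "lf_scores",
    "overall_lf_scores",
    "validate_trajectory",
    "position_snapshots",
    "field_distribution",
    "transitivity",
    "group_cohesion",
]

ROLE_POINTS = {"profitable": 3, "neutral": 2, "unprofitable": 1}


@dataclass(frozen=True)
class MoveEvent:
    """One single-cell movement step; ``event_index`` orders moves in a round."""

    round: int
    event_index: int
    player: str
    from_cell: HexCell
    to_cell: HexCell

    def __post_init__(self):
        if self.from_cell == self.to_cell:
            raise TrajectoryError(
                f"round {self.round} event {self.event_index}: move of {self.player!r} "
                "does not change the cell"
            )


@dataclass(frozen=True)
class RoundChoice:
    """One player's option choice in one round; ``option=None`` is a missed
    round and carries no payout."""

    round: int
    player: str
    option: int | None
    payout_cent: int = 0
    bonus_cent: int = 0

    def __post_init__(self):
        if self.option is None and self.payout_cent != 0:
            raise ValueError(
                f"round {self.round}: missed round of {self.player!r} cannot pay out"
            )


@dataclass(frozen=True)
class PlayerScores:
    """Derived per-player statistics."""

    player: str
    choice_score: int
    half_change_round: int
    n_changes: int
    lf_total: int | None = None


@dataclass(frozen=True)
class GroupCohesion:
    """Spatial-cohesion summary of one session."""

    field_distribution_pct: float
    field_distribution_move_pct: float
    transitivity: float | None = None


# ---------------------------------------------------------------------------
# card-choice metrics


def _ordered_choices(choices: Sequence[RoundChoice]) -> list[RoundChoice]:
    if not choices:
        raise EmptyInputError("no round choices for this player")
    ordered = sorted(choices, key=lambda c: c.round)
    rounds = [c.round for c in ordered]
    if len(set(rounds)) != len(rounds):
        raise ValueError(f"duplicate rounds in choice sequence: {rounds}")
    return ordered


def choice_score(
    choices: Sequence[RoundChoice],
    option_roles: Mapping[int, str],
) -> int:
    """Sum of per-round decision-quality points for one player.

    Profitable option: 3 points, neutral: 2, unprofitable: 1, missed round
    (``option=None``): 0.
    """
    total = 0
    for c in _ordered_choices(choices):
        if c.option is None:
            continue
        role = option_roles.get(c.option)
        if role not in ROLE_POINTS:
            raise ValueError(
                f"round {c.round}: option {c.option} has unknown role {role!r}"
            )
        total += ROLE_POINTS[role]
    return total


def _change_rounds(choices: Sequence[RoundChoice]) -> list[int]:
    """Rounds in which the player's chosen option differs from the most
    recent prior actual choice (missed rounds never count as changes)."""
    changes = []
    prev: int | None = None
    for c in _ordered_choices(choices):
        if c.option is None:
            continue
        if prev is not None and c.option != prev:
            changes.append(c.round)
        prev = c.option
    return changes


def half_change_round(choices: Sequence[RoundChoice]) -> int:
    """Smallest round by which at least half of all option changes occurred.

    A player that never changes option gets round 1 (immediate exploitation
    convention); callers can detect that case via ``n_changes`` in
    :func:`player_scores`.
    """
    changes = _change_rounds(choices)
    if not changes:
        return 1
    needed = math.ceil(len(changes) / 2)
    return changes[needed - 1]


def player_scores(
    choices_by_player: Mapping[str, Sequence[RoundChoice]],
    option_roles: Mapping[int, str],
    lf_totals: Mapping[str, int] | None = None,
) -> list[PlayerScores]:
    """Bundle the per-player card metrics (and optional L-F totals)."""
    out = []
    for player, choices in choices_by_player.items():
        out.append(
            PlayerScores(
                player=player,
                choice_score=choice_score(choices, option_roles),
                half_change_round=half_change_round(choices),
                n_changes=len(_change_rounds(choices)),
                lf_total=None if lf_totals is None else lf_totals.get(player),
            )
        )
    return out


# ---------------------------------------------------------------------------
# movement metrics


def _sorted_moves(moves: Iterable[MoveEvent]) -> list[MoveEvent]:
    moves = list(moves)
    key = lambda m: (m.round, m.event_index)
    ordered = sorted(moves, key=key)
    seen = set()
    for m in ordered:
        if (m.round, m.event_index) in seen:
            raise TrajectoryError(
                f"round {m.round} event {m.event_index}: duplicate event index"
            )
        seen.add((m.round, m.event_index))
    return ordered


def validate_trajectory(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
    board: HexBoard | None = None,
) -> list[MoveEvent]:
    """Check that every move starts where its player currently stands (and
    stays on the board, if one is given); returns the ordered event list.

    Raises :class:`TrajectoryError` naming the offending event otherwise.
    """
    pos = dict(initial_positions)
    if not pos:
        raise EmptyInputError("no initial positions")
    if board is not None:
        for player, cell in pos.items():
            if not board.contains(cell):
                raise TrajectoryError(
                    f"initial position of {player!r} {tuple(cell)} is off the board"
                )
    ordered = _sorted_moves(moves)
    for m in ordered:
        if m.player not in pos:
            raise TrajectoryError(
                f"round {m.round} event {m.event_index}: unknown player {m.player!r}"
            )
        if pos[m.player] != m.from_cell:
            raise TrajectoryError(
                f"round {m.round} event {m.event_index}: {m.player!r} moves from "
                f"{tuple(m.from_cell)} but stands on {tuple(pos[m.player])}"
            )
        if board is not None and not board.contains(m.to_cell):
            raise TrajectoryError(
                f"round {m.round} event {m.event_index}: target {tuple(m.to_cell)} "
                "is off the board"
            )
        pos[m.player] = m.to_cell
    return ordered


def lf_increments(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
) -> list[tuple[MoveEvent, dict[str, int]]]:
    """Per-move L-F score increments for every player.

    For each move by mover ``m`` and every other player ``o``, the change in
    their pairwise distance decides the increment: moving away (+1 mover,
    −1 other), moving closer (−1 mover, +1 other), unchanged distance (0, 0).
    The increments of a single move always sum to zero across players.
    """
    pos = dict(initial_positions)
    out = []
    for m in validate_trajectory(moves, initial_positions):
        inc = {p: 0 for p in pos}
        for other, cell in pos.items():
            if other == m.player:
                continue
            delta = hex_distance(m.to_cell, cell) - hex_distance(m.from_cell, cell)
            if delta > 0:
                inc[m.player] += 1
                inc[other] -= 1
            elif delta < 0:
                inc[m.player] -= 1
                inc[other] += 1
        pos[m.player] = m.to_cell
        out.append((m, inc))
    return out


def lf_scores(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
    n_rounds: int | None = None,
) -> pd.DataFrame:
    """Per-round L-F scores, one row per round, one column per player.

    Every player starts each round at zero; rounds without moves stay all
    zero.  Summing over rounds gives the overall L-F score
    (:func:`overall_lf_scores`).
    """
    players = sorted(initial_positions)
    incs = lf_increments(moves, initial_positions)
    max_round = max((m.round for m, _ in incs), default=0)
    n_rounds = max(n_rounds or 0, max_round, 1)
    table = pd.DataFrame(
        0, index=pd.RangeIndex(1, n_rounds + 1, name="round"), columns=players
    )
    for m, inc in incs:
        for player, delta in inc.items():
            table.loc[m.round, player] += delta
    return table


def overall_lf_scores(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
) -> dict[str, int]:
    """Overall L-F score per player: per-round scores summed over all rounds."""
    table = lf_scores(moves, initial_positions)
    return {p: int(v) for p, v in table.sum(axis=0).items()}


def position_snapshots(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
    include_initial: bool = True,
) -> list[dict[str, HexCell]]:
    """Player-position snapshots: the initial placement (optional) plus one
    snapshot after every move event."""
    pos = dict(initial_positions)
    snaps = [dict(pos)] if include_initial else []
    for m in validate_trajectory(moves, initial_positions):
        pos[m.player] = m.to_cell
        snaps.append(dict(pos))
    return snaps


def field_distribution(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
    board: HexBoard,
) -> GroupCohesion:
    """Spatial-distribution percentages of one session.

    Game level: percent of board cells occupied by any player at any time.
    Move level: mean over snapshots of the percent of cells currently
    occupied.  An empty trajectory is scored from the initial placement alone.
    """
    snaps = position_snapshots(moves, initial_positions, include_initial=True)
    used: set[HexCell] = set()
    per_snapshot = []
    for snap in snaps:
        cells = set(snap.values())
        used |= cells
        per_snapshot.append(100.0 * len(cells) / board.n_cells)
    return GroupCohesion(
        field_distribution_pct=100.0 * len(used) / board.n_cells,
        field_distribution_move_pct=float(np.mean(per_snapshot)),
    )


def _snapshot_transitivity(positions: Mapping[str, HexCell], weight: str) -> float:
    players = sorted(positions)
    if len(players) < 3:
        raise ValueError(f"transitivity needs >= 3 players, got {len(players)}")
    g = nx.Graph()
    g.add_nodes_from(players)
    for i, a in enumerate(players):
        for b in players[i + 1 :]:
            d = hex_distance(positions[a], positions[b])
            if weight == "inv1p":
                w = 1.0 / (1.0 + d)
            elif weight == "inv_clamped":
                w = 1.0 / max(d, 1)
            else:
                raise ValueError(f"unknown weight scheme {weight!r}")
            g.add_edge(a, b, weight=w)
    # Onnela geometric-mean triangle intensity, averaged over nodes; weights
    # are normalized by the maximum edge weight inside nx.clustering.
    cc = nx.clustering(g, weight="weight")
    return float(np.mean(list(cc.values())))


def transitivity(
    positions: Mapping[str, HexCell] | Sequence[Mapping[str, HexCell]],
    weight: str = "inv1p",
) -> float:
    """Global weighted clustering coefficient of the player-proximity graph.

    Players form a complete graph weighted by inverted distance
    (``1/(1+d)`` by default; ``weight='inv_clamped'`` uses ``1/max(d, 1)``).
    Clustering is the Onnela geometric-mean triangle intensity averaged over
    nodes; a sequence of snapshots yields the mean over snapshots.  Equals 1
    whenever all pairwise distances are equal.
    """
    if isinstance(positions, Mapping):
        return _snapshot_transitivity(positions, weight)
    snaps = list(positions)
    if not snaps:
        raise EmptyInputError("no position snapshots")
    return float(np.mean([_snapshot_transitivity(s, weight) for s in snaps]))


def group_cohesion(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
    board: HexBoard,
    weight: str = "inv1p",
) -> GroupCohesion:
    """Field-distribution percentages plus snapshot-averaged transitivity."""
    dist = field_distribution(moves, initial_positions, board)
    snaps = position_snapshots(moves, initial_positions, include_initial=True)
    return GroupCohesion(
        field_distribution_pct=dist.field_distribution_pct,
        field_distribution_move_pct=dist.field_distribution_move_pct,
        transitivity=transitivity(snaps, weight=weight),
    )
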