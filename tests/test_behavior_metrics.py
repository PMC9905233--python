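"""Behavioral metrics: choice score, half-change round, L-F score, cohesion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohesim import (
    EmptyInputError,
    HexBoard,
    HexCell,
    MoveEvent,
    OPTION_ROLES,
    RoundChoice,
    TrajectoryError,
    choice_score,
    field_distribution,
    group_cohesion,
    half_change_round,
    hex_distance,
    lf_increments,
    lf_scores,
    overall_lf_scores,
    player_scores,
    position_snapshots,
    transitivity,
    validate_trajectory,
)


def _choices(options, player="p1", start_round=1):
    """Build a per-player choice sequence from a list of option ids/None."""
    return [
        RoundChoice(start_round + i, player, opt)
        for i, opt in enumerate(options)
    ]


class TestChoiceScore:
    def test_all_profitable_scores_three_per_round(self):
        assert choice_score(_choices([0] * 30), OPTION_ROLES) == 90

    def test_mixed_roles_and_missed_rounds(self):
        opts = [0] * 10 + [1] * 5 + [2] * 5 + [3] * 5 + [None] * 5
        # 10*3 + 10*2 + 5*1 + 0
        assert choice_score(_choices(opts), OPTION_ROLES) == 55

    def test_all_missed_scores_zero(self):
        assert choice_score(_choices([None] * 30), OPTION_ROLES) == 0

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError, match="unknown role"):
            choice_score(_choices([7]), OPTION_ROLES)

    def test_duplicate_round_rejected(self):
        dup = [RoundChoice(1, "p1", 0), RoundChoice(1, "p1", 1)]
        with pytest.raises(ValueError, match="duplicate"):
            choice_score(dup, OPTION_ROLES)

    def test_bounds(self):
        n = 30
        assert 0 <= choice_score(_choices([3] * n), OPTION_ROLES) <= 3 * n


class TestHalfChangeRound:
    def test_four_changes_midpoint(self):
        # changes occur in rounds 2,3,4,5: half of 4 changes reached in round 3
        assert half_change_round(_choices([0, 1, 0, 1, 0, 0, 0])) == 3

    def test_single_change(self):
        opts = [0] * 9 + [1] + [1] * 20
        assert half_change_round(_choices(opts)) == 10

    def test_constant_choices_convention(self):
        assert half_change_round(_choices([2] * 30)) == 1

    def test_missed_rounds_do_not_count_as_changes(self):
        # 0, miss, 0, 1: only one change (round 4); misses never break streaks
        assert half_change_round(_choices([0, None, 0, 1])) == 4
        # 0, miss, 1: change registered at round 3 against the round-1 choice
        assert half_change_round(_choices([0, None, 1])) == 3

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            half_change_round([])

    def test_range_invariant(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            opts = [int(o) for o in rng.integers(0, 4, n)]
            assert 1 <= half_change_round(_choices(opts)) <= n


class TestLFScores:
    def test_worked_example(self, lf_worked_example):
        moves, initial = lf_worked_example
        incs = lf_increments(moves, initial)
        # move 1: A leads away from both others (pairwise rule), B and C lose
        assert incs[0][1] == {"A": 2, "B": -1, "C": -1}
        # move 2: B follows A (A +1) while abandoning C (C -1); B cancels out
        assert incs[1][1] == {"A": 1, "B": 0, "C": -1}
        totals = overall_lf_scores(moves, initial)
        assert totals == {"A": 3, "B": -1, "C": -2}
        assert sum(totals.values()) == 0

    def test_no_moves_all_zero(self):
        initial = {"A": HexCell(0, 0), "B": HexCell(1, 0), "C": HexCell(0, 1)}
        table = lf_scores([], initial, n_rounds=5)
        assert (table.to_numpy() == 0).all()
        assert len(table) == 5

    def test_round_reset(self, lf_worked_example):
        moves, initial = lf_worked_example
        later = [
            MoveEvent(2, 1, "C", HexCell(0, 0), HexCell(1, 0)),
        ]
        table = lf_scores(moves + later, initial)
        assert table.loc[1].sum() == 0 and table.loc[2].sum() == 0
        assert table.loc[1, "A"] == 3  # round 1 unchanged by round 2 moves

    def test_inconsistent_trajectory_names_event(self):
        initial = {"A": HexCell(0, 0), "B": HexCell(1, 0), "C": HexCell(0, 1)}
        bad = [MoveEvent(1, 1, "A", HexCell(3, 0), HexCell(4, 0))]
        with pytest.raises(TrajectoryError, match="round 1 event 1"):
            lf_increments(bad, initial)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_zero_sum_on_random_walks(self, data):
        """Per-move L-F increments sum to zero over players for arbitrary
        consistent trajectories (pairwise +1/-1 bookkeeping)."""
        board = HexBoard(4)
        players = ["a", "b", "c", "d"]
        cells = list(board.cells())
        idx = data.draw(
            st.lists(st.integers(0, len(cells) - 1), min_size=4, max_size=4, unique=True)
        )
        pos = {p: cells[i] for p, i in zip(players, idx)}
        initial = dict(pos)
        moves = []
        n_moves = data.draw(st.integers(1, 25))
        for e in range(1, n_moves + 1):
            p = data.draw(st.sampled_from(players))
            nb = data.draw(st.sampled_from(board.neighbors(pos[p])))
            moves.append(MoveEvent(1, e, p, pos[p], nb))
            pos[p] = nb
        for _, inc in lf_increments(moves, initial):
            assert sum(inc.values()) == 0
        assert sum(overall_lf_scores(moves, initial).values()) == 0


class TestFieldDistribution:
    def test_static_players_game_level(self):
        board = HexBoard(5)
        initial = {f"p{i}": cell for i, cell in enumerate(board.ring(1))}
        dist = field_distribution([], initial, board)
        assert dist.field_distribution_pct == pytest.approx(6 / 91 * 100)
        assert dist.field_distribution_move_pct == pytest.approx(6 / 91 * 100)

    def test_stacked_players_move_level(self):
        board = HexBoard(5)
        initial = {f"p{i}": HexCell(0, 0) for i in range(6)}
        dist = field_distribution([], initial, board)
        assert dist.field_distribution_move_pct == pytest.approx(1 / 91 * 100)

    def test_full_coverage(self):
        board = HexBoard(1)  # 7 cells; the ring cells are pairwise adjacent
        path = [HexCell(0, 0)] + board.neighbors(HexCell(0, 0))
        moves = [
            MoveEvent(1, e, "a", a, b)
            for e, (a, b) in enumerate(zip(path, path[1:]), start=1)
        ]
        dist = field_distribution(moves, {"a": path[0]}, board)
        assert dist.field_distribution_pct == pytest.approx(100.0)


class TestTransitivity:
    def test_colocated_players_maximal(self):
        pos = {p: HexCell(0, 0) for p in "abcd"}
        assert transitivity(pos) == pytest.approx(1.0)

    def test_equidistant_players_maximal(self):
        pos = {"a": HexCell(0, 0), "b": HexCell(1, 0), "c": HexCell(0, 1)}
        assert transitivity(pos) == pytest.approx(1.0)

    def test_matches_brute_force_triangle_enumeration(self):
        """Independent O(n^3) Onnela-intensity computation on hand-placed
        players agrees with the packaged network-based implementation."""
        pos = {
            "a": HexCell(0, 0),
            "b": HexCell(3, 0),
            "c": HexCell(0, 4),
            "d": HexCell(-2, 1),
        }
        players = sorted(pos)
        w = {}
        for i, j in itertools.combinations(players, 2):
            w[(i, j)] = w[(j, i)] = 1.0 / (1.0 + hex_distance(pos[i], pos[j]))
        w_max = max(w.values())
        cc = []
        for i in players:
            others = [p for p in players if p != i]
            k = len(others)
            total = 0.0
            for j, l in itertools.combinations(others, 2):
                total += (
                    (w[(i, j)] / w_max) * (w[(i, l)] / w_max) * (w[(j, l)] / w_max)
                ) ** (1.0 / 3.0)
            cc.append(2.0 * total / (k * (k - 1)))
        assert transitivity(pos) == pytest.approx(float(np.mean(cc)), abs=1e-12)

    def test_dispersed_below_stacked(self):
        board = HexBoard(5)
        stacked = {p: HexCell(0, 0) for p in "abcdef"}
        corners = board.corners()
        spread = {p: corners[i] for i, p in enumerate("abcdef")}
        assert transitivity(stacked) == pytest.approx(1.0)
        assert transitivity(spread) < 1.0

    def test_snapshot_sequence_averages(self):
        a = {p: HexCell(0, 0) for p in "abc"}
        b = {"a": HexCell(0, 0), "b": HexCell(2, 0), "c": HexCell(-1, 3)}
        mean = transitivity([a, b])
        assert mean == pytest.approx((transitivity(a) + transitivity(b)) / 2)

    def test_too_few_players(self):
        with pytest.raises(ValueError, match=">= 3"):
            transitivity({"a": HexCell(0, 0), "b": HexCell(1, 0)})


class TestPermutationEquivariance:
    def test_relabeling_players(self, lf_worked_example):
        moves, initial = lf_worked_example
        relabel = {"A": "Z", "B": "Y", "C": "X"}
        moves2 = [
            MoveEvent(m.round, m.event_index, relabel[m.player], m.from_cell, m.to_cell)
            for m in moves
        ]
        initial2 = {relabel[p]: c for p, c in initial.items()}
        t1 = overall_lf_scores(moves, initial)
        t2 = overall_lf_scores(moves2, initial2)
        assert t2 == {relabel[p]: v for p, v in t1.items()}
        board = HexBoard(5)
        g1 = group_cohesion(moves, initial, board)
        g2 = group_cohesion(moves2, initial2, board)
        assert g1 == g2


class TestPlayerScores:
    def test_bundle(self):
        by_player = {
            "p1": _choices([0] * 30, "p1"),
            "p2": _choices([0, 1] * 15, "p2"),
        }
        scores = {s.player: s for s in player_scores(by_player, OPTION_ROLES)}
        assert scores["p1"].choice_score == 90
        assert scores["p1"].half_change_round == 1  # never changed
        assert scores["p1"].n_changes == 0
        assert scores["p2"].n_changes == 29
        assert 1 <= scores["p2"].half_change_round <= 30


class TestValidateTrajectory:
    def test_off_board_rejected(self):
        board = HexBoard(2)
        initial = {"a": HexCell(2, 0)}
        bad = [MoveEvent(1, 1, "a", HexCell(2, 0), HexCell(3, 0))]
        with pytest.raises(TrajectoryError, match="off the board"):
            validate_trajectory(bad, initial, board)

    def test_snapshots_track_positions(self, lf_worked_example):
        moves, initial = lf_worked_example
        snaps = position_snapshots(moves, initial)
        assert len(snaps) == 3
        assert snaps[0]["A"] == HexCell(2, 0)
        assert snaps[1]["A"] == HexCell(3, 0)
        assert snaps[2]["B"] == HexCell(2, 0)
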