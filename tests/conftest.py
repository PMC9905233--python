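"""Shared fixtures: deterministic RNGs and small constructed sessions."""

import numpy as np
import pytest

from cohesim import HexCell, MoveEvent


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lf_worked_example():
    """Three players on a line; A leads away, then B follows A away from C.

    Move 1: A steps away from both B and C.  Move 2: B steps toward A but
    away from C, so B's increments cancel, A gains a point for being
    followed, and C keeps losing.
    """
    initial = {"A": HexCell(2, 0), "B": HexCell(1, 0), "C": HexCell(0, 0)}
    moves = [
        MoveEvent(1, 1, "A", HexCell(2, 0), HexCell(3, 0)),
        MoveEvent(1, 2, "B", HexCell(1, 0), HexCell(2, 0)),
    ]
    return moves, initial
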