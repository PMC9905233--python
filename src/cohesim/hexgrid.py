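"""Axial-coordinate hexagonal board geometry.

The playing field is a regular hexagon of configurable radius ``R`` centred on
the origin, containing every axial cell ``(q, r)`` with
``|q| <= R``, ``|r| <= R`` and ``|q + r| <= R`` — ``3R(R+1) + 1`` cells in
total (91 for the default radius 5).  Distances are counted in fields, i.e.
the minimum number of single-cell steps between two cells.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple

from .errors import ConfigError


class HexCell(NamedTuple):
    """One cell of the board in axial coordinates, (0, 0) at the centre."""

    q: int
    r: int


#: The six axial direction vectors, clockwise from "east".
AXIAL_DIRECTIONS: tuple[HexCell, ...] = (
    HexCell(1, 0),
    HexCell(1, -1),
    HexCell(0, -1),
    HexCell(-1, 0),
    HexCell(-1, 1),
    HexCell(0, 1),
)


def hex_distance(a: HexCell, b: HexCell) -> int:
    """Number of fields between two cells (axial hex metric).

    Equals ``(|dq| + |dr| + |dq + dr|) / 2``; symmetric, zero iff ``a == b``,
    and satisfies the triangle inequality.
    """
    dq = a.q - b.q
    dr = a.r - b.r
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def axial_to_xy(cell: HexCell) -> tuple[float, float]:
    """Planar (pointy-top) coordinates of a cell centre, unit cell spacing."""
    x = cell.q + cell.r / 2.0
    y = cell.r * 0.8660254037844386  # sqrt(3)/2
    return x, y


class HexBoard:
    """Regular hexagonal board of a given radius.

    Parameters
    ----------
    radius:
        Number of rings around the central cell; radius 5 gives the 91-cell
        default board.
    """

    def __init__(self, radius: int = 5):
        if radius < 1:
            raise ConfigError(f"board radius must be >= 1, got {radius}")
        self.radius = int(radius)

    @property
    def n_cells(self) -> int:
        r = self.radius
        return 3 * r * (r + 1) + 1

    def contains(self, cell: HexCell) -> bool:
        r = self.radius
        return abs(cell.q) <= r and abs(cell.r) <= r and abs(cell.q + cell.r) <= r

    def require(self, cell: HexCell) -> HexCell:
        """Return ``cell`` unchanged or raise if it is off the board."""
        if not self.contains(cell):
            raise ConfigError(f"cell {tuple(cell)} is off the radius-{self.radius} board")
        return cell

    def cells(self) -> Iterator[HexCell]:
        r = self.radius
        for q in range(-r, r + 1):
            for s in range(max(-r, -q - r), min(r, -q + r) + 1):
                yield HexCell(q, s)

    def neighbors(self, cell: HexCell) -> list[HexCell]:
        out = []
        for d in AXIAL_DIRECTIONS:
            nb = HexCell(cell.q + d.q, cell.r + d.r)
            if self.contains(nb):
                out.append(nb)
        return out

    def ring(self, distance: int) -> list[HexCell]:
        """All cells at a given distance from the centre."""
        return [c for c in self.cells() if hex_distance(c, HexCell(0, 0)) == distance]

    def corners(self) -> list[HexCell]:
        """The six outermost corner cells."""
        r = self.radius
        return [
            HexCell(r, 0), HexCell(r, -r), HexCell(0, -r),
            HexCell(-r, 0), HexCell(-r, r), HexCell(0, r),
        ]
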