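"""CSV/JSON/YAML readers and writers, and the reproducibility manifest.

CSV dialects (UTF-8, LF, name-keyed columns so column order is free):

* choices:   ``round,player,option,payout_cent,bonus_cent`` — empty ``option``
  marks a missed round;
* moves:     ``round,event_index,player,from_q,from_r,to_q,to_r``;
* positions: ``player,q,r`` (initial placements; players that never move do
  not appear in the moves file, so positions are stored separately);
* simulator output: ``run,iteration,agent,choice,payout_cent,bonus_cent``
  plus per-iteration counts ``run,iteration,option,count``.

Every CLI command drops a ``manifest.json`` (config snapshot, seed, package
version, SHA-256 of each written file); re-running a deterministic stage with
the manifest's config and seed reproduces the checksums byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import MoveEvent, RoundChoice, validate_trajectory
from .errors import SchemaError, TrajectoryError
from .hexgrid import HexBoard, HexCell

logger = logging.getLogger("cohesim")

__all__ = [
    "RunManifest",
    "read_choices",
    "write_choices",
    "read_trajectory",
    "write_trajectory",
    "write_tables",
    "load_config",
    "write_manifest",
    "verify_manifest",
]

CHOICES_COLUMNS = ["round", "player", "option", "payout_cent", "bonus_cent"]
MOVES_COLUMNS = ["round", "event_index", "player", "from_q", "from_r", "to_q", "to_r"]
POSITIONS_COLUMNS = ["player", "q", "r"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def read_choices(path) -> list[RoundChoice]:
    """Read a round-choice log; returns records ordered by (round, player)."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty choice log", path)
        return []
    _require_columns(df, CHOICES_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            option = None if pd.isna(row["option"]) else int(row["option"])
            out.append(
                RoundChoice(
                    round=int(row["round"]),
                    player=str(row["player"]),
                    option=option,
                    payout_cent=int(row["payout_cent"]),
                    bonus_cent=int(row["bonus_cent"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed row {i + 2}: {exc}") from exc
    return sorted(out, key=lambda c: (c.round, c.player))


def write_choices(choices: Iterable[RoundChoice], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            (c.round, c.player, c.option, c.payout_cent, c.bonus_cent)
            for c in choices
        ],
        columns=CHOICES_COLUMNS,
    )
    df["option"] = df["option"].astype("Int64")
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_trajectory(
    moves_path,
    positions_path=None,
    board: HexBoard | None = None,
) -> tuple[list[MoveEvent], dict[str, HexCell]]:
    """Read a movement log (plus initial positions) and validate it.

    Without a positions file, each player's initial cell is inferred from its
    first ``from`` cell, which only covers players that move at least once.
    Malformed rows, off-board cells and discontinuous trajectories raise
    errors naming the offending row/event.
    """
    df = pd.read_csv(moves_path)
    if df.empty and positions_path is None:
        logger.warning("%s: empty movement log", moves_path)
        return [], {}
    if not df.empty:
        _require_columns(df, MOVES_COLUMNS, moves_path)
    moves = []
    for i, row in df.iterrows():
        try:
            moves.append(
                MoveEvent(
                    round=int(row["round"]),
                    event_index=int(row["event_index"]),
                    player=str(row["player"]),
                    from_cell=HexCell(int(row["from_q"]), int(row["from_r"])),
                    to_cell=HexCell(int(row["to_q"]), int(row["to_r"])),
                )
            )
        except TrajectoryError as exc:
            raise TrajectoryError(f"{moves_path}: row {i + 2}: {exc}") from exc
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{moves_path}: malformed row {i + 2}: {exc}") from exc
    if positions_path is not None:
        pos_df = pd.read_csv(positions_path)
        _require_columns(pos_df, POSITIONS_COLUMNS, positions_path)
        initial = {
            str(r["player"]): HexCell(int(r["q"]), int(r["r"]))
            for _, r in pos_df.iterrows()
        }
    else:
        initial = {}
        for m in sorted(moves, key=lambda m: (m.round, m.event_index)):
            initial.setdefault(m.player, m.from_cell)
    moves = validate_trajectory(moves, initial, board)
    return moves, initial


def write_trajectory(
    moves: Iterable[MoveEvent],
    initial_positions: Mapping[str, HexCell],
    moves_path,
    positions_path,
) -> tuple[Path, Path]:
    moves_path, positions_path = Path(moves_path), Path(positions_path)
    pd.DataFrame(
        [
            (m.round, m.event_index, m.player, m.from_cell.q, m.from_cell.r,
             m.to_cell.q, m.to_cell.r)
            for m in moves
        ],
        columns=MOVES_COLUMNS,
    ).to_csv(moves_path, index=False, lineterminator="\n")
    pd.DataFrame(
        [(p, c.q, c.r) for p, c in sorted(initial_positions.items())],
        columns=POSITIONS_COLUMNS,
    ).to_csv(positions_path, index=False, lineterminator="\n")
    return moves_path, positions_path


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write named DataFrames as ``<name>.csv`` with deterministic columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".json",):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Snapshot of one CLI run: config, seed, version, output checksums."""

    command: str
    config: dict
    seed: int | None
    version: str
    created: str
    files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def write_manifest(
    out_dir, command: str, config: dict, seed: int | None, files: Iterable[Path]
) -> Path:
    out_dir = Path(out_dir)
    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
        files={Path(f).name: _sha256(Path(f)) for f in files},
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json() + "\n", encoding="utf-8")
    return path


def verify_manifest(out_dir) -> bool:
    """Re-hash the files recorded in ``manifest.json``; True iff all match."""
    out_dir = Path(out_dir)
    data = json.loads((out_dir / "manifest.json").read_text(encoding="utf-8"))
    return all(
        _sha256(out_dir / name) == digest for name, digest in data["files"].items()
    )
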