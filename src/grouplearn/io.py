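"""File formats: YAML layouts, trajectory logs, cohort tables.

Trajectory log schema (one row per timestep)::

    participant_id,level_id,t,x,y,action,item_colour,item_shape

Coordinates are 0-based (x, y) with the origin top-left. The item columns
are empty except on the collecting row (the final step of a trajectory that
ended on an item).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .gridworld import GridWorld, ItemType, Trajectory, _ACTION_DELTA

TRAJECTORY_COLUMNS = [
    "participant_id", "level_id", "t", "x", "y", "action",
    "item_colour", "item_shape",
]


class SchemaError(ValueError):
    """A malformed input table or layout file."""


def layout_to_dict(grid: GridWorld) -> dict:
    return {
        "width": grid.width,
        "height": grid.height,
        "walls": [list(c) for c in sorted(grid.walls)],
        "items": [
            {"cell": list(c), "colour": it.colour, "shape": it.shape}
            for c, it in sorted(grid.items.items())
        ],
        "start_cells": [list(c) for c in grid.start_cells],
        "level_id": grid.level_id,
    }


def save_layout(grid: GridWorld, path) -> None:
    Path(path).write_text(yaml.safe_dump(layout_to_dict(grid), sort_keys=False))


def load_layout(path) -> GridWorld:
    data = yaml.safe_load(Path(path).read_text())
    try:
        return GridWorld(
            width=data["width"],
            height=data["height"],
            walls=frozenset(tuple(c) for c in data.get("walls", [])),
            items={
                tuple(e["cell"]): ItemType(colour=e["colour"], shape=e["shape"])
                for e in data["items"]
            },
            start_cells=tuple(tuple(c) for c in data.get("start_cells", [])),
            level_id=data.get("level_id", "level"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed layout file {path}: {exc}") from exc


def write_trajectories(trajectories: Iterable[Trajectory], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRAJECTORY_COLUMNS)
        for traj in trajectories:
            n = len(traj.steps)
            for t, (cell, action) in enumerate(traj.steps):
                collecting = t == n - 1 and traj.collected_item is not None
                w.writerow([
                    traj.agent_id, traj.level_id, t, cell[0], cell[1], action,
                    traj.collected_item.colour if collecting else "",
                    traj.collected_item.shape if collecting else "",
                ])


def read_trajectories(path) -> list:
    """Parse a trajectory log back into Trajectory objects.

    The end cell is reconstructed by applying the last action's move (the
    collecting move is never wall-blocked in the generated levels).
    """
    rows_by_key: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != TRAJECTORY_COLUMNS:
            raise SchemaError(
                f"unexpected header {reader.fieldnames} in {path}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["participant_id"], row["level_id"])
                rows_by_key.setdefault(key, []).append((
                    int(row["t"]), int(row["x"]), int(row["y"]), row["action"],
                    row["item_colour"], row["item_shape"],
                ))
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"row {i} of {path}: {exc}") from exc
    out = []
    for (pid, level), rows in rows_by_key.items():
        rows.sort()
        steps = [((x, y), a) for _, x, y, a, _, _ in rows]
        collected = None
        _, x, y, a, ic, ish = rows[-1]
        if ic:
            collected = ItemType(colour=ic, shape=ish)
        dx, dy = _ACTION_DELTA[a]
        out.append(Trajectory(
            agent_id=pid, level_id=level, steps=steps,
            end_cell=(x + dx, y + dy), collected_item=collected,
        ))
    return out


def save_group_presets(groups: Mapping, path) -> None:
    """Write a {label: GroupParams} preset as YAML."""
    data = {
        label: {
            "utility_mean": list(g.utility_mean),
            "utility_sd": list(g.utility_sd),
            "cue_mean": g.cue_mean,
            "cue_sd": g.cue_sd,
        }
        for label, g in groups.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_group_presets(path) -> dict:
    from .population import GroupParams

    data = yaml.safe_load(Path(path).read_text())
    try:
        return {
            label: GroupParams(
                utility_mean=tuple(v["utility_mean"]),
                utility_sd=tuple(v["utility_sd"]),
                cue_mean=float(v["cue_mean"]),
                cue_sd=float(v["cue_sd"]),
            )
            for label, v in data.items()
        }
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed group preset {path}: {exc}") from exc


def write_participants(rows: Iterable[Mapping], path) -> None:
    """participants.csv: id, condition, utility weights, cue, strategy, seed."""
    rows = list(rows)
    cols = ["participant_id", "experiment", "condition", "u_colour", "u_shape",
            "phi", "strategy", "seed"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for r in rows:
            w.writerow({c: r.get(c, "") for c in cols})
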