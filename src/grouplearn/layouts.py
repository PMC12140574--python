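"""Procedural gridworld layouts for the choice experiments.

The published experiments used hand-built levels whose exact geometry is not
available, so layouts are generated procedurally under the constraint that
the two options are equidistant from the start unless a level is explicitly
built with unequal arm lengths (needed to make the 'closest item' heuristic
non-degenerate).
"""

from __future__ import annotations

from .gridworld import DEFAULT_FEATURES, FeatureSpace, GridWorld, ItemType

#: default grid size for the two-choice levels
WIDTH = 9
HEIGHT = 9
START = (4, 7)
LEFT_CELL = (1, 1)
RIGHT_CELL = (7, 1)
#: right-hand item cell for levels with unequal arm lengths (closer option)
RIGHT_CELL_NEAR = (7, 5)


def two_item_level(
    level_id: str,
    left_item: ItemType,
    right_item: ItemType,
    hidden: bool = False,
    uneven: bool = False,
    features: FeatureSpace = DEFAULT_FEATURES,
) -> GridWorld:
    """A two-choice level: one item in each upper arm, start at bottom centre.

    Both items are 9 moves from the start; with ``uneven`` the right item is
    moved closer (5 moves). ``hidden`` marks a mystery-box test level: the
    layout itself is identical, visibility is handled by the experiment
    bookkeeping, not the MDP.
    """
    right = RIGHT_CELL_NEAR if uneven else RIGHT_CELL
    tag = f"{level_id}{'[hidden]' if hidden else ''}"
    return GridWorld(
        width=WIDTH,
        height=HEIGHT,
        walls=frozenset(),
        items={LEFT_CELL: left_item, right: right_item},
        start_cells=(START,),
        level_id=tag,
        features=features,
    )


def four_goal_grid(size: int = 7) -> GridWorld:
    """The four-goal arena used for the imitation return surface.

    One item of each feature combination sits in each corner; demonstrators
    start from randomised interior cells.
    """
    items = {
        (0, 0): ItemType(colour="green", shape="triangle"),
        (size - 1, 0): ItemType(colour="yellow", shape="triangle"),
        (0, size - 1): ItemType(colour="green", shape="circle"),
        (size - 1, size - 1): ItemType(colour="yellow", shape="circle"),
    }
    starts = tuple(
        (x, y)
        for x in range(size)
        for y in range(size)
        if (x, y) not in items
    )
    return GridWorld(
        width=size,
        height=size,
        items=items,
        start_cells=starts,
        level_id="four-goal",
    )
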