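import numpy as np
import pytest

from grouplearn.gridworld import GridWorld, ItemType, UtilityFunction


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def one_step_grid():
    """3x1 corridor with an item one move right of the start."""
    return GridWorld(
        width=3,
        height=1,
        items={(1, 0): ItemType("yellow", "circle")},
        start_cells=((0, 0),),
        level_id="corridor",
    )


@pytest.fixture
def two_item_3x3():
    """3x3 grid with a yellow and a green item in opposite corners."""
    return GridWorld(
        width=3,
        height=3,
        items={
            (0, 0): ItemType("yellow", "triangle"),
            (2, 0): ItemType("green", "triangle"),
        },
        start_cells=((1, 2),),
        level_id="choice3x3",
    )


@pytest.fixture
def colour_lover():
    """Strong yellow preference, indifferent to shape."""
    return UtilityFunction(weights=(0.9, 0.5))


@pytest.fixture
def colour_hater():
    return UtilityFunction(weights=(0.1, 0.5))
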