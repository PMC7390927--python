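import numpy as np
import pytest

from ptgrid.env import (GridSpec, Orientation, Pose, ScenarioSpec, WorldState)


@pytest.fixture
def grid11():
    return GridSpec(11, 11)


@pytest.fixture
def toy_scenario():
    """2x2 shared spawn area with a 3-cell subordinate column on a 5x5
    grid: small enough for exhaustive checks (144 configurations)."""
    return ScenarioSpec(
        grid=GridSpec(5, 5),
        subordinate_cells=((0, 0), (1, 0), (2, 0)),
        subordinate_orientation=Orientation.EAST,
        dominant_area=(2, 2, 3, 3),
        food_area=(2, 2, 3, 3),
    )


@pytest.fixture
def scenario_4x4():
    """Tiny scenario on a 4x4 grid for exhaustive rollout oracles."""
    return ScenarioSpec(
        grid=GridSpec(4, 4),
        subordinate_cells=((0, 0), (1, 0), (2, 0), (3, 0)),
        subordinate_orientation=Orientation.EAST,
        dominant_area=(1, 1, 2, 2),
        food_area=(1, 1, 2, 2),
    )


def make_state(grid_n, sub, dom, food):
    """Shorthand state constructor: sub/dom are (row, col, Orientation)."""
    return WorldState(
        grid=GridSpec(grid_n, grid_n),
        subordinate=Pose(sub[0], sub[1], sub[2]),
        dominant=Pose(dom[0], dom[1], dom[2]),
        food_pos=food,
    )
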