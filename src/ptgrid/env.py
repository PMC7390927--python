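"""Grid-world food-competition environment.

Two agents — a static *Dominant* and a learning *Subordinate* — share a
square grid with a single food item.  The Subordinate is rewarded for
eating the food only when the food lies outside the Dominant's 180-degree
field of view; eating observed food is heavily punished.  This module
holds the world state, the spawn-rule scenario generator (which doubles
as the package's synthetic-data source), field-of-view geometry, step
dynamics and the optimal-reward oracle used as a reference line in
learning curves.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
North decreases the row index, East increases the column index.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "Orientation",
    "GridSpec",
    "Pose",
    "WorldState",
    "ScenarioSpec",
    "RewardSpec",
    "StepOutcome",
    "visible_cells",
    "food_observed_by_dominant",
    "enumerate_initial_configs",
    "sample_initial_state",
    "ScenarioSampler",
    "step",
    "optimal_episode_reward",
    "render_ascii",
]


class Orientation(IntEnum):
    """Cardinal heading; integer order matches the one-hot layout
    (North, South, East, West) used by the observation encoders."""

    NORTH = 0
    SOUTH = 1
    EAST = 2
    WEST = 3

    @property
    def vector(self) -> tuple[int, int]:
        return _ORIENT_VEC[self]


_ORIENT_VEC = {
    Orientation.NORTH: (-1, 0),
    Orientation.SOUTH: (1, 0),
    Orientation.EAST: (0, 1),
    Orientation.WEST: (0, -1),
}


@dataclass(frozen=True)
class GridSpec:
    """Square grid dimensions (13x13 for allocentric-vision runs, 11x11
    for egocentric-vision runs; other sizes are allowed for tests)."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows != self.n_cols:
            raise ValueError("grid must be square")

    @property
    def n(self) -> int:
        return self.n_rows

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclass(frozen=True)
class Pose:
    row: int
    col: int
    orientation: Orientation


@dataclass(frozen=True)
class WorldState:
    """Full environment state.

    The Dominant is static for the whole episode, so
    ``food_observed_by_dominant`` is fixed at spawn and cached here.
    ``food_pos`` becomes ``None`` once the food has been eaten.
    """

    grid: GridSpec
    subordinate: Pose
    dominant: Pose
    food_pos: tuple[int, int] | None
    step_count: int = 0
    food_observed: bool | None = None

    def __post_init__(self) -> None:
        for pose in (self.subordinate, self.dominant):
            if not self.grid.contains(pose.row, pose.col):
                raise ValueError(f"pose {pose} out of bounds for {self.grid}")
        if self.food_pos is not None:
            if not self.grid.contains(*self.food_pos):
                raise ValueError("food position out of bounds")
            cells = {
                (self.dominant.row, self.dominant.col),
                self.food_pos,
            }
            if len(cells) < 2:
                raise ValueError("dominant and food may not overlap")
        if self.food_observed is None and self.food_pos is not None:
            object.__setattr__(
                self, "food_observed", food_observed_by_dominant(self, _from_init=True)
            )


@dataclass(frozen=True)
class RewardSpec:
    """Reward values: eating food the Dominant can see costs -1000,
    eating unobserved food pays +1000, and every time step costs 0.1.
    Episodes are cut off after ``max_steps`` (default 100) steps."""

    eat_observed: float = -1000.0
    eat_unobserved: float = 1000.0
    step_cost: float = -0.1
    max_steps: int = 100

    def __post_init__(self) -> None:
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")


class DoneReason(IntEnum):
    NONE = 0
    ATE_FOOD = 1
    TIMEOUT = 2


@dataclass(frozen=True)
class StepOutcome:
    next_state: WorldState
    reward: float
    done: bool
    done_reason: DoneReason


def _rect_cells(rect: tuple[int, int, int, int]) -> list[tuple[int, int]]:
    r0, c0, r1, c1 = rect
    return [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]


@dataclass(frozen=True)
class ScenarioSpec:
    """Spawn rules for initial configurations.

    Defaults follow the main task: the Subordinate spawns anywhere in the
    leftmost column facing East, while the Dominant and the food spawn
    anywhere inside a 5x5 area centred on the grid, with no overlaps.
    Rectangles are inclusive ``(row0, col0, row1, col1)``.
    """

    grid: GridSpec
    subordinate_cells: tuple[tuple[int, int], ...]
    subordinate_orientation: Orientation
    dominant_area: tuple[int, int, int, int]
    food_area: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for r, c in self.subordinate_cells:
            if not self.grid.contains(r, c):
                raise ValueError("subordinate spawn cell out of grid")
        for rect in (self.dominant_area, self.food_area):
            r0, c0, r1, c1 = rect
            if not (self.grid.contains(r0, c0) and self.grid.contains(r1, c1)):
                raise ValueError("spawn rectangle exceeds grid")
            if r1 < r0 or c1 < c0:
                raise ValueError("degenerate spawn rectangle")

    @classmethod
    def default(cls, grid_n: int, spawn_n: int = 5) -> "ScenarioSpec":
        """Main-task scenario on an ``grid_n`` x ``grid_n`` grid with a
        centred ``spawn_n`` x ``spawn_n`` shared spawn area (5x5 sits at
        rows/cols 3-7 on 11x11 and 4-8 on 13x13)."""
        grid = GridSpec(grid_n, grid_n)
        off = (grid_n - spawn_n) // 2
        area = (off, off, off + spawn_n - 1, off + spawn_n - 1)
        sub_cells = tuple((r, 0) for r in range(grid_n))
        return cls(grid, sub_cells, Orientation.EAST, area, area)

    @classmethod
    def from_yaml(cls, path: str) -> tuple["ScenarioSpec", RewardSpec]:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        grid = GridSpec(cfg["grid_n"], cfg["grid_n"])
        sub_cells = tuple(tuple(c) for c in cfg.get(
            "subordinate_cells", [(r, 0) for r in range(grid.n)]))
        scenario = cls(
            grid,
            sub_cells,
            Orientation[cfg.get("subordinate_orientation", "EAST")],
            tuple(cfg["dominant_area"]),
            tuple(cfg["food_area"]),
        )
        rw = cfg.get("rewards", {})
        rewards = RewardSpec(
            eat_observed=rw.get("eat_observed", -1000.0),
            eat_unobserved=rw.get("eat_unobserved", 1000.0),
            step_cost=rw.get("step_cost", -0.1),
            max_steps=rw.get("max_steps", 100),
        )
        return scenario, rewards


# ---------------------------------------------------------------------------
# Field of view
# ---------------------------------------------------------------------------

def visible_cells(pose: Pose, grid: GridSpec) -> np.ndarray:
    """Boolean mask of the cells inside a 180-degree field of view.

    Vision range is unlimited and there are no obstacles, so the visual
    field is the closed half-plane in front of the agent: for an agent
    facing East every cell with ``col >= pose.col`` is visible, and
    analogously for the other headings.  The agent's own cell is always
    visible (the boundary line is included).
    """
    if not grid.contains(pose.row, pose.col):
        raise ValueError(f"pose {pose} out of bounds")
    rows = np.arange(grid.n_rows)[:, None]
    cols = np.arange(grid.n_cols)[None, :]
    dr, dc = pose.orientation.vector
    # dot((cell - pose), heading) >= 0
    return (dr * (rows - pose.row) + dc * (cols - pose.col)) >= 0


def food_observed_by_dominant(state: WorldState, *, _from_init: bool = False) -> bool:
    """Whether the food lies inside the Dominant's field of view.

    This is the quantity the Subordinate must infer: it decides the sign
    of the eating reward.  Raises if the food has been consumed.
    """
    if state.food_pos is None:
        raise ValueError("food has been consumed; visibility query invalid")
    if not _from_init and state.food_observed is not None:
        return state.food_observed
    mask = visible_cells(state.dominant, state.grid)
    return bool(mask[state.food_pos])


# ---------------------------------------------------------------------------
# Scenario enumeration and sampling
# ---------------------------------------------------------------------------

def enumerate_initial_configs(scenario: ScenarioSpec) -> list[WorldState]:
    """All initial configurations, in deterministic lexicographic order:
    food cell x dominant cell x dominant orientation x subordinate cell,
    skipping any placement where two elements share a cell.
    """
    food_cells = _rect_cells(scenario.food_area)
    dom_cells = _rect_cells(scenario.dominant_area)
    if not food_cells or not dom_cells or not scenario.subordinate_cells:
        raise ValueError("empty spawn set")
    states = []
    for food in food_cells:
        for dom in dom_cells:
            if dom == food:
                continue
            for orient in Orientation:
                for sub in scenario.subordinate_cells:
                    if sub == food or sub == dom:
                        continue
                    states.append(
                        WorldState(
                            grid=scenario.grid,
                            subordinate=Pose(*sub, scenario.subordinate_orientation),
                            dominant=Pose(*dom, orient),
                            food_pos=food,
                        )
                    )
    return states


def sample_initial_state(scenario: ScenarioSpec, rng: np.random.Generator | int) -> WorldState:
    """Draw one initial configuration uniformly over the enumerated set."""
    return ScenarioSampler(scenario).sample(rng)


class ScenarioSampler:
    """Enumerates a scenario once and draws uniform initial states.

    Used by the training loop, where per-episode re-enumeration would be
    wasteful."""

    def __init__(self, scenario: ScenarioSpec):
        self.scenario = scenario
        self.states = enumerate_initial_configs(scenario)
        if not self.states:
            raise ValueError("scenario admits no initial configuration")

    def sample(self, rng: np.random.Generator | int) -> WorldState:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return self.states[int(rng.integers(len(self.states)))]


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

_VALID_DISPLACEMENTS = {(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}


def step(
    state: WorldState,
    world_displacement: tuple[int, int],
    new_orientation: Orientation,
    rewards: RewardSpec = RewardSpec(),
) -> StepOutcome:
    """Advance the world by one Subordinate action.

    ``world_displacement`` is the attempted move in world coordinates
    (one cell in a cardinal direction, or none); frame-relative actions
    are translated by :mod:`ptgrid.encodings` before reaching here.  A
    move onto an off-grid cell or the Dominant's cell is blocked — the
    position is unchanged but the orientation still updates, keeping the
    "always looks where it heads" coupling unconditional.  Every step
    costs ``step_cost``; landing on the food additionally pays
    ``eat_unobserved`` or ``eat_observed`` and ends the episode, as does
    reaching ``max_steps``.
    """
    if state.food_pos is None:
        raise ValueError("step() called on a terminated episode (food eaten)")
    if state.step_count >= rewards.max_steps:
        raise ValueError("step() called on a terminated episode (timeout)")
    if tuple(world_displacement) not in _VALID_DISPLACEMENTS:
        raise ValueError(f"invalid displacement {world_displacement}")

    r = state.subordinate.row + world_displacement[0]
    c = state.subordinate.col + world_displacement[1]
    blocked = (not state.grid.contains(r, c)) or (r, c) == (
        state.dominant.row,
        state.dominant.col,
    )
    if blocked:
        r, c = state.subordinate.row, state.subordinate.col

    reward = rewards.step_cost
    ate = (r, c) == state.food_pos
    new_count = state.step_count + 1
    if ate:
        reward += rewards.eat_unobserved if not state.food_observed else rewards.eat_observed
        reason = DoneReason.ATE_FOOD
    elif new_count >= rewards.max_steps:
        reason = DoneReason.TIMEOUT
    else:
        reason = DoneReason.NONE

    next_state = dataclasses.replace(
        state,
        subordinate=Pose(r, c, new_orientation),
        food_pos=None if ate else state.food_pos,
        step_count=new_count,
        food_observed=state.food_observed,
    )
    return StepOutcome(next_state, reward, reason != DoneReason.NONE, reason)


# ---------------------------------------------------------------------------
# Optimal-reward oracle
# ---------------------------------------------------------------------------

def _shortest_path_steps(state: WorldState) -> int:
    """Moves needed to reach the food, detouring around the Dominant.

    With a single static obstacle on a rectangular grid the distance is
    the Manhattan distance, plus 2 exactly when start and food share a
    row or column with the Dominant strictly between them (every
    monotone shortest path is then blocked and a one-cell sidestep is
    required).
    """
    (sr, sc) = state.subordinate.row, state.subordinate.col
    (fr, fc) = state.food_pos
    (dr, dc) = state.dominant.row, state.dominant.col
    d = abs(sr - fr) + abs(sc - fc)
    blocked = (
        sr == fr == dr and min(sc, fc) < dc < max(sc, fc)
    ) or (
        sc == fc == dc and min(sr, fr) < dr < max(sr, fr)
    )
    if blocked and state.grid.n == 1:  # no sidestep room; cannot happen in practice
        raise ValueError("food unreachable")
    return d + (2 if blocked else 0)


def optimal_episode_reward(state: WorldState, rewards: RewardSpec = RewardSpec()) -> float:
    """Best achievable episode return from an initial state.

    If the Dominant observes the food the best policy never eats and
    simply pays the step cost for the whole episode; otherwise it walks
    a shortest path to the food.  Identical for both action frames since
    every action displaces one cell in any world direction.
    """
    if state.step_count != 0:
        raise ValueError("oracle expects an initial state")
    if state.food_observed:
        return rewards.max_steps * rewards.step_cost
    d = _shortest_path_steps(state)
    return rewards.eat_unobserved + d * rewards.step_cost


# ---------------------------------------------------------------------------
# Debug output
# ---------------------------------------------------------------------------

_GLYPH = {Orientation.NORTH: "^", Orientation.SOUTH: "v",
          Orientation.EAST: ">", Orientation.WEST: "<"}


def render_ascii(state: WorldState) -> str:
    """Plain-text frame: S/D with heading glyphs, F for food, dots for
    cells inside the Subordinate's field of view."""
    fov = visible_cells(state.subordinate, state.grid)
    rows = []
    for r in range(state.grid.n_rows):
        line = []
        for c in range(state.grid.n_cols):
            if (r, c) == (state.subordinate.row, state.subordinate.col):
                line.append("S" + _GLYPH[state.subordinate.orientation])
            elif (r, c) == (state.dominant.row, state.dominant.col):
                line.append("D" + _GLYPH[state.dominant.orientation])
            elif state.food_pos == (r, c):
                line.append("F ")
            else:
                line.append(". " if fov[r, c] else "  ")
        rows.append("".join(line))
    return "\n".join(rows)


def dump_trajectory_jsonl(records: Sequence[dict], path: str) -> None:
    """Write one JSON object per step (state, action, reward) for debugging."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
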