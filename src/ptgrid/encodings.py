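"""Visual and motor encodings: allocentric vs. egocentric frames.

The network never sees the raw world state.  It sees binary occupancy
maps plus orientation one-hot vectors, in one of two visual frames:

* **allocentric** — a fixed top-down camera; four n x n maps (Dominant,
  Subordinate, food, observability) at world coordinates, plus a
  world-frame orientation one-hot for each agent.
* **egocentric** — the world as seen from the Subordinate, rotated so
  that it always faces frame-up and anchored at the bottom-centre of an
  n x (2n-1) frame; three maps (Dominant, food, observability — no self
  map, the agent is always at its own origin) plus the Dominant's
  orientation *relative* to the Subordinate's heading.

Entities outside the Subordinate's 180-degree field of view are absent
from every map, and — in the egocentric frame — an unobserved Dominant
also contributes an all-zero relative-orientation vector: the
information is truly missing, so any use of it must come from memory.

Motor actions come in the same two frames (North/South/East/West/no-move
vs. forward/backward/right/left/no-move); either way each move displaces
one cell and rotates the agent to face the direction of travel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .env import GridSpec, Orientation, Pose, WorldState, visible_cells

__all__ = [
    "RelativeOrientation",
    "AllocentricObservation",
    "EgocentricObservation",
    "ALLO_ACTIONS",
    "EGO_ACTIONS",
    "N_ACTIONS",
    "relative_orientation",
    "world_to_ego_frame",
    "build_allocentric_observation",
    "build_egocentric_observation",
    "build_observation",
    "action_to_world",
    "observation_shapes",
]

N_ACTIONS = 5

ALLO_ACTIONS = ("north", "south", "east", "west", "no_move")
EGO_ACTIONS = ("forward", "backward", "right", "left", "no_move")


class RelativeOrientation(IntEnum):
    """Dominant heading relative to the Subordinate's: facing toward it
    (opposite headings), the same direction, to its left (90 degrees
    counter-clockwise) or to its right (90 degrees clockwise)."""

    TOWARD = 0
    SAME = 1
    LEFT = 2
    RIGHT = 3


def _ccw(v: tuple[int, int]) -> tuple[int, int]:
    # 90-degree counter-clockwise rotation on screen axes (row grows down)
    return (-v[1], v[0])


def relative_orientation(
    dominant: Orientation, subordinate: Orientation
) -> RelativeOrientation:
    """Classify the Dominant's heading relative to the Subordinate's.

    Defined by heading relation, not by where the Dominant's position
    lies: "toward" means the headings are opposite.
    """
    dv, sv = dominant.vector, subordinate.vector
    if dv == sv:
        return RelativeOrientation.SAME
    if dv == (-sv[0], -sv[1]):
        return RelativeOrientation.TOWARD
    if dv == _ccw(sv):
        return RelativeOrientation.LEFT
    return RelativeOrientation.RIGHT


def world_to_ego_frame(
    world_cell: tuple[int, int], subordinate: Pose, grid: GridSpec
) -> tuple[int, int] | None:
    """Map a world cell into the Subordinate's n x (2n-1) visual frame.

    The world is rotated so the Subordinate faces frame-up; the agent is
    anchored at frame cell ``(n-1, n-1)`` (bottom centre).  Returns
    ``None`` for cells strictly behind the agent, which fall outside the
    180-degree frame.
    """
    if not grid.contains(*world_cell):
        raise ValueError("world cell out of grid")
    n = grid.n
    hv = subordinate.orientation.vector
    rv = (hv[1], -hv[0])  # 90-degree clockwise of heading = agent's right
    dr = world_cell[0] - subordinate.row
    dc = world_cell[1] - subordinate.col
    forward = dr * hv[0] + dc * hv[1]
    rightward = dr * rv[0] + dc * rv[1]
    if forward < 0:
        return None
    return (n - 1 - forward, n - 1 + rightward)


@dataclass(frozen=True)
class AllocentricObservation:
    """World-frame maps (each n x n) and per-agent orientation one-hots
    in (North, South, East, West) order."""

    dominant_map: np.ndarray
    subordinate_map: np.ndarray
    food_map: np.ndarray
    observability_map: np.ndarray
    dominant_orientation: np.ndarray
    subordinate_orientation: np.ndarray

    def maps(self) -> np.ndarray:
        """Stack as (H, W, C) with channel order dominant, subordinate,
        food, observability — the network's input layout."""
        return np.stack(
            [self.dominant_map, self.subordinate_map,
             self.food_map, self.observability_map], axis=-1)

    def orientations(self) -> np.ndarray:
        return np.concatenate(
            [self.dominant_orientation, self.subordinate_orientation])


@dataclass(frozen=True)
class EgocentricObservation:
    """Self-centred maps (each n x (2n-1)); no self map or self
    orientation — the agent is always at the frame anchor facing up."""

    dominant_map: np.ndarray
    food_map: np.ndarray
    observability_map: np.ndarray
    dominant_relative_orientation: np.ndarray

    def maps(self) -> np.ndarray:
        """(H, W, C) stack, channel order dominant, food, observability."""
        return np.stack(
            [self.dominant_map, self.food_map, self.observability_map], axis=-1)

    def orientations(self) -> np.ndarray:
        return self.dominant_relative_orientation


def _one_hot(index: int, size: int = 4) -> np.ndarray:
    v = np.zeros(size, dtype=np.uint8)
    v[index] = 1
    return v


def build_allocentric_observation(state: WorldState) -> AllocentricObservation:
    """Top-down maps masked by the Subordinate's field of view.

    The Dominant and the food appear only when the Subordinate sees
    them; the Subordinate's own cell is always inside its own FOV.
    An unobserved Dominant also has an all-zero orientation vector.
    """
    n = state.grid.n
    fov = visible_cells(state.subordinate, state.grid)
    dom = np.zeros((n, n), dtype=np.uint8)
    sub = np.zeros((n, n), dtype=np.uint8)
    food = np.zeros((n, n), dtype=np.uint8)
    sub[state.subordinate.row, state.subordinate.col] = 1
    dom_visible = fov[state.dominant.row, state.dominant.col]
    if dom_visible:
        dom[state.dominant.row, state.dominant.col] = 1
    if state.food_pos is not None and fov[state.food_pos]:
        food[state.food_pos] = 1
    dom_orient = (
        _one_hot(state.dominant.orientation)
        if dom_visible else np.zeros(4, dtype=np.uint8)
    )
    return AllocentricObservation(
        dominant_map=dom,
        subordinate_map=sub,
        food_map=food,
        observability_map=fov.astype(np.uint8),
        dominant_orientation=dom_orient,
        subordinate_orientation=_one_hot(state.subordinate.orientation),
    )


def build_egocentric_observation(state: WorldState) -> EgocentricObservation:
    """Self-centred maps of shape n x (2n-1).

    Only the in-bounds half-plane in front of the agent is populated;
    frame cells with no world counterpart (beyond the grid edge) stay
    zero in the observability map, distinguishing "empty but seen" from
    "not seen at all".
    """
    n = state.grid.n
    shape = (n, 2 * n - 1)
    dom = np.zeros(shape, dtype=np.uint8)
    food = np.zeros(shape, dtype=np.uint8)
    obs = np.zeros(shape, dtype=np.uint8)
    sub = state.subordinate
    fov = visible_cells(sub, state.grid)
    # vectorized frame transform of every visible cell (hot path during
    # episode collection)
    hv = sub.orientation.vector
    rv = (hv[1], -hv[0])
    rr, cc = np.nonzero(fov)
    dr, dc = rr - sub.row, cc - sub.col
    fi = (n - 1) - (dr * hv[0] + dc * hv[1])
    fj = (n - 1) + (dr * rv[0] + dc * rv[1])
    obs[fi, fj] = 1
    dom_visible = fov[state.dominant.row, state.dominant.col]
    if dom_visible:
        dom[world_to_ego_frame((state.dominant.row, state.dominant.col),
                               sub, state.grid)] = 1
    if state.food_pos is not None and fov[state.food_pos]:
        food[world_to_ego_frame(state.food_pos, sub, state.grid)] = 1
    rel = (
        _one_hot(relative_orientation(state.dominant.orientation, sub.orientation))
        if dom_visible else np.zeros(4, dtype=np.uint8)
    )
    return EgocentricObservation(
        dominant_map=dom, food_map=food, observability_map=obs,
        dominant_relative_orientation=rel)


def build_observation(state: WorldState, vision_frame: str):
    if vision_frame == "allo":
        return build_allocentric_observation(state)
    if vision_frame == "ego":
        return build_egocentric_observation(state)
    raise ValueError(f"unknown vision frame {vision_frame!r}")


def observation_shapes(vision_frame: str, grid_n: int) -> tuple[tuple[int, int, int], int]:
    """(map stack shape (H, W, C), orientation vector length)."""
    if vision_frame == "allo":
        return (grid_n, grid_n, 4), 8
    if vision_frame == "ego":
        return (grid_n, 2 * grid_n - 1, 3), 4
    raise ValueError(f"unknown vision frame {vision_frame!r}")


# ---------------------------------------------------------------------------
# Action translation
# ---------------------------------------------------------------------------

_ALLO_DIR = {
    0: Orientation.NORTH,
    1: Orientation.SOUTH,
    2: Orientation.EAST,
    3: Orientation.WEST,
}


def action_to_world(
    action: int, action_frame: str, current: Orientation
) -> tuple[tuple[int, int], Orientation]:
    """Translate a frame-relative action index into a world displacement
    and the agent's resulting heading.

    Allocentric actions move in fixed world directions; egocentric
    actions move relative to the current heading (backward turns the
    agent around).  Every move sets the heading to the direction of
    travel; no-move keeps the current heading in both frames.
    """
    if not 0 <= action < N_ACTIONS:
        raise ValueError(f"action index {action} out of range")
    if action == 4:  # no-move
        return (0, 0), current
    if action_frame == "allo":
        new = _ALLO_DIR[action]
        return new.vector, new
    if action_frame == "ego":
        hv = current.vector
        rel = {
            0: hv,                      # forward
            1: (-hv[0], -hv[1]),        # backward
            2: (hv[1], -hv[0]),         # right (clockwise of heading)
            3: (-hv[1], hv[0]),         # left
        }[action]
        new = next(o for o in Orientation if o.vector == rel)
        return rel, new
    raise ValueError(f"unknown action frame {action_frame!r}")
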