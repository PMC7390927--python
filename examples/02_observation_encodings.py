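"""Compare the allocentric and egocentric views of one world state.

The allocentric observation is a fixed top-down camera: n x n maps at
world coordinates plus world-frame orientation one-hots.  The
egocentric observation rotates the world so the Subordinate faces
frame-up, anchored at the bottom centre of an n x (2n-1) frame, and
encodes the Dominant's orientation relative to the agent's own heading.
Entities outside the Subordinate's 180-degree field of view vanish from
both encodings.
"""

import numpy as np

from ptgrid.encodings import (build_allocentric_observation,
                              build_egocentric_observation)
from ptgrid.env import GridSpec, Orientation, Pose, WorldState

state = WorldState(
    grid=GridSpec(11, 11),
    subordinate=Pose(5, 2, Orientation.EAST),
    dominant=Pose(4, 6, Orientation.WEST),
    food_pos=(7, 5),
)

allo = build_allocentric_observation(state)
ego = build_egocentric_observation(state)

print("allocentric maps:", allo.maps().shape, "orientations:",
      allo.orientations().shape)
print("egocentric maps: ", ego.maps().shape, "orientations:",
      ego.orientations().shape)
print("\nvisible cells:", int(allo.observability_map.sum()),
      "(same count in both frames:", int(ego.observability_map.sum()), ")")
print("Dominant faces West, Subordinate faces East ->",
      "relative orientation one-hot", ego.dominant_relative_orientation,
      "(toward, same, left, right)")
print("food at world", np.argwhere(allo.food_map)[0],
      "-> egocentric frame cell", np.argwhere(ego.food_map)[0],
      "(row 10 = the agent's own row, column 10 = straight ahead)")
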