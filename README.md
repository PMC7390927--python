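# ptgrid — perspective taking in a grid-world food competition

`ptgrid` is a research package for studying a minimal form of
*perspective taking* — acting on what another agent can or cannot see —
in reinforcement-learning agents.  A **Subordinate** agent shares a
square grid world with a static **Dominant** agent and a single food
item.  Both agents have unlimited-range, 180°-field-of-view vision.
Eating food that the Dominant *cannot* see pays **+1000**; eating food
it *can* see costs **−1000**; every time step costs **−0.1**; episodes
end when the food is eaten or after 100 steps.  Solving the task
requires integrating the Dominant's position and orientation with the
food's position — a grid-world analogue of food-competition experiments
with chimpanzees.

The scientific question is representational: is this skill easier to
learn with **allocentric** (fixed top-down map) or **egocentric**
(self-centred, rotating-with-the-agent) encodings of vision and action?
The package implements all four visuomotor combinations and the
analyses to compare them.

## What's inside

| module | contents |
| --- | --- |
| `ptgrid.env` | world state, spawn-rule scenario enumeration/sampling, 180° half-plane visibility, step dynamics and rewards, optimal-reward oracle |
| `ptgrid.encodings` | binary observation maps in both visual frames (n×n allocentric, n×(2n−1) egocentric), relative-orientation coding, frame-relative action translation |
| `ptgrid.nn` | NumPy neural-network core: valid 3×3 convolution, dense layers, LSTM with backpropagation through time, Adam, global-norm gradient clipping |
| `ptgrid.agent` | the dueling recurrent Q-network `Q = V + (A − max A)`, ε-greedy policy, linear ε annealing, soft target updates, checkpointing |
| `ptgrid.training` | padded-trajectory replay (capacity 1000), masked TD(0) loss, the full RL loop |
| `ptgrid.supervised` | the visibility-classification baseline: every initial configuration, labelled with whether the Dominant sees the food, learned by the LSTM-free network |
| `ptgrid.evaluate` | behavioral correctness over all enumerated configurations, reward curves with the optimal-reward reference, layer-wise LDA probing |

The network (one 3×3 convolution with 6 filters → merge with
orientation one-hots → two 32-unit layers → 128-cell LSTM → 32-unit
layer → value and advantage heads) is implemented directly on NumPy;
every backward pass is verified against finite differences in the test
suite.

## Worked example

```python
from ptgrid.env import ScenarioSpec, sample_initial_state, optimal_episode_reward

scenario = ScenarioSpec.default(11)          # 11x11 world, centred 5x5 spawn area
state = sample_initial_state(scenario, 42)
print(state.food_observed)                    # True
print(optimal_episode_reward(state))          # -10.0
```

Here the Dominant happens to see the food, so the best the Subordinate
can do is never touch it and pay 100 × (−0.1) = −10.0.  Had the food
been hidden, the optimum would be +1000 minus 0.1 per step of the
shortest path (e.g. 999.6 at Manhattan distance 4).

The `examples/` scripts each demonstrate one capability end to end
(world and rewards, the two encodings, supervised visibility
classification, a desk-scale RL run with reward curves, layer probes).
For long runs there is a thin CLI:

```bash
ptgrid train --vision ego --action ego --steps 200000 --seed 0
ptgrid supervised --frame allo --epochs 4 --inits 20
ptgrid evaluate --checkpoint checkpoint.npz --action ego
ptgrid probe --checkpoint checkpoint.npz
```

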