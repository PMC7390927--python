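"""Spawn a scenario, render it, and walk through an episode.

Builds the default egocentric-scale world (11x11, centred 5x5 spawn
area), samples an initial configuration, prints the ASCII frame, and
steps a hand-chosen action sequence, showing the reward ledger: -0.1
per step, +/-1000 (plus the step cost) on eating, depending on whether
the Dominant observes the food.
"""

from ptgrid.env import (RewardSpec, ScenarioSpec, optimal_episode_reward,
                        render_ascii, sample_initial_state, step)
from ptgrid.evaluate import OraclePolicy

scenario = ScenarioSpec.default(11)
state = sample_initial_state(scenario, 42)
print(render_ascii(state))
print(f"\nfood observed by Dominant: {state.food_observed}")
print(f"optimal episode reward:     {optimal_episode_reward(state):+.1f}")
print("  (+999.x means: sneak to the food; -10.0 means: never touch it)\n")

policy = OraclePolicy()
policy.reset()
total, done = 0.0, False
while not done:
    disp, orient = policy.act(state)
    out = step(state, disp, orient, RewardSpec())
    total += out.reward
    state = out.next_state
    done = out.done
print(f"oracle rollout: {state.step_count} steps, return {total:+.1f}, "
      f"ended by {out.done_reason.name}")
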