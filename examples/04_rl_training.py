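"""Desk-scale reinforcement learning run with reward curves.

Trains the ego-vision/ego-action condition on a 5x5 world for 30,000
environment steps (a few minutes on one CPU), then prints per-100-
episode mean rewards next to the best-achievable reference.  The agent
reward approaching the reference from below is the learning signal; at
full scale the protocol is 2e7 steps on an 11x11 world over 7 seeds.
"""

import numpy as np

from ptgrid.env import ScenarioSpec
from ptgrid.evaluate import GreedyQPolicy, evaluate_policy, reward_curve
from ptgrid.training import TrainConfig, run_training

cfg = TrainConfig(vision_frame="ego", action_frame="ego", grid_n=5,
                  spawn_n=3, total_steps=30_000, seed=0)
scenario = ScenarioSpec.default(5, 3)
net, log = run_training(cfg, scenario=scenario)

agent, oracle = reward_curve(log.episode_reward, log.optimal_reward)
print("bin  agent_mean  best_achievable")
for i in range(0, len(agent), max(1, len(agent) // 10)):
    print(f"{i:3d}  {agent[i]:+10.1f}  {oracle[i]:+10.1f}")

report = evaluate_policy(GreedyQPolicy(net, cfg.action_frame), scenario)
print(f"\ngreedy evaluation over all {report.n_should_eat + report.n_should_avoid} "
      f"configurations: {report.pct_correct_approach:.1f}% correct approach, "
      f"{report.pct_correct_avoid:.1f}% correct avoid")
print("(correct approach = ate unobserved food; correct avoid = left "
      "observed food alone)")
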