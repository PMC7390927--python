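"""Where in the network does "does the Dominant see the food?" live?

Trains a small agent, then fits a linear discriminant on each layer's
first-time-step activations to decode the food-visibility bit, layer by
layer: input, flatten (post-convolution), merge (with orientations),
FC_1, FC_2, LSTM, FC_3, output (the Q-values).
"""

from ptgrid.env import ScenarioSpec, enumerate_initial_configs
from ptgrid.evaluate import collect_activations, linear_probe_layers
from ptgrid.training import TrainConfig, run_training

scenario = ScenarioSpec.default(7, 3)
cfg = TrainConfig(vision_frame="ego", action_frame="ego", grid_n=7,
                  spawn_n=3, total_steps=20_000, seed=0)
net, _ = run_training(cfg, scenario=scenario)

states = enumerate_initial_configs(scenario)
acts, labels = collect_activations(net, states)
report = linear_probe_layers(acts, labels, split_seed=0)

print(f"probed {len(states)} configurations "
      f"({100 * labels.mean():.0f}% labelled 'observed')")
for layer in report.layers:
    bar = "#" * int(40 * report.accuracy[layer])
    print(f"{layer:8s} {report.accuracy[layer]:.3f} {bar}")
print("\naccuracy above the majority-class rate means the visibility "
      "bit is linearly decodable at that depth")
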