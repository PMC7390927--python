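"""Behavioral evaluation, reward curves and layer-wise linear probing.

Three analyses of a trained (or hand-coded) Subordinate policy:

* **Behavioral correctness** — greedy rollouts from *every* enumerated
  initial configuration, classified by trial type: should-eat (food not
  observed by the Dominant) vs. should-avoid, scoring the percentage of
  trials where the food was obtained within the episode limit
  respectively never obtained.
* **Reward curves** — per-100-episode mean training reward next to the
  mean best-achievable reward of the same episodes (the oracle
  reference line).
* **Linear probing** — linear discriminant analysis fit on the
  activations of each named layer (input, flatten, merge, FC_1, FC_2,
  LSTM, FC_3, output) at the first time step, measuring how decodable
  the food-visibility bit is at each processing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .agent import PROBE_LAYERS, DuelingQNet
from .encodings import action_to_world, build_observation
from .env import (Pose, RewardSpec, ScenarioSpec, WorldState,
                  enumerate_initial_configs, step)

__all__ = [
    "EvalReport",
    "ProbeReport",
    "GreedyQPolicy",
    "OraclePolicy",
    "StandStillPolicy",
    "evaluate_policy",
    "reward_curve",
    "collect_activations",
    "linear_probe_layers",
]


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------

class GreedyQPolicy:
    """Epsilon = 0 policy of a Q-network, with a fresh recurrent state
    per episode."""

    def __init__(self, net: DuelingQNet, action_frame: str):
        self.net = net
        self.action_frame = action_frame
        self._h = None
        self._c = None

    def reset(self) -> None:
        self._h, self._c = self.net.init_state(1)

    def act(self, state: WorldState):
        obs = build_observation(state, self.net.vision_frame)
        q, self._h, self._c = self.net.forward_q(
            obs.maps()[None], obs.orientations()[None], self._h, self._c)
        action = int(np.argmax(q[0]))
        return action_to_world(action, self.action_frame,
                               state.subordinate.orientation)


class OraclePolicy:
    """Ground-truth reference: shortest path to the food when it should
    be eaten, stand still when it should be avoided."""

    def reset(self) -> None:
        pass

    @staticmethod
    def _dist(r, c, fr, fc, dr, dc):
        # shortest-path length with the Dominant as the single obstacle:
        # Manhattan, +2 when it blocks the degenerate (collinear) corridor
        d = abs(r - fr) + abs(c - fc)
        blocked = (r == fr == dr and min(c, fc) < dc < max(c, fc)) or (
            c == fc == dc and min(r, fr) < dr < max(r, fr))
        return d + (2 if blocked else 0)

    def act(self, state: WorldState):
        if state.food_observed or state.food_pos is None:
            return (0, 0), state.subordinate.orientation
        sr, sc = state.subordinate.row, state.subordinate.col
        fr, fc = state.food_pos
        dr, dc = state.dominant.row, state.dominant.col
        best = None
        for action in range(4):
            disp, orient = action_to_world(action, "allo",
                                           state.subordinate.orientation)
            r, c = sr + disp[0], sc + disp[1]
            if not state.grid.contains(r, c) or (r, c) == (dr, dc):
                continue
            d = self._dist(r, c, fr, fc, dr, dc)
            if best is None or d < best[0]:
                best = (d, disp, orient)
        return best[1], best[2]


class StandStillPolicy:
    def reset(self) -> None:
        pass

    def act(self, state: WorldState):
        return (0, 0), state.subordinate.orientation


# ---------------------------------------------------------------------------
# Behavioral evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Correct-behavior percentages by trial type, with per-trial records."""

    n_should_eat: int
    n_should_avoid: int
    pct_correct_approach: float
    pct_correct_avoid: float
    trials: list = field(default_factory=list)

    def __str__(self) -> str:
        return (f"should-eat trials: {self.n_should_eat} "
                f"({self.pct_correct_approach:.2f}% correct approach); "
                f"should-avoid trials: {self.n_should_avoid} "
                f"({self.pct_correct_avoid:.2f}% correct avoid)")


def evaluate_policy(policy, scenario: ScenarioSpec,
                    rewards: RewardSpec = RewardSpec(),
                    keep_trials: bool = False) -> EvalReport:
    """Roll out a policy greedily from every enumerated configuration.

    A trial counts as *correct approach* when the food is not observed
    by the Dominant and the policy obtains it within the episode limit,
    and as *correct avoid* when observed food is never obtained.
    """
    if isinstance(policy, GreedyQPolicy) and policy.net.grid_n != scenario.grid.n:
        raise ValueError("checkpoint grid size does not match scenario")
    n_eat = n_avoid = ok_eat = ok_avoid = 0
    trials = []
    for init in enumerate_initial_configs(scenario):
        policy.reset()
        state = init
        ate = False
        done = False
        while not done:
            disp, orient = policy.act(state)
            outcome = step(state, disp, orient, rewards)
            state = outcome.next_state
            done = outcome.done
            ate = outcome.done_reason.name == "ATE_FOOD"
        should_eat = not init.food_observed
        correct = ate if should_eat else not ate
        if should_eat:
            n_eat += 1
            ok_eat += correct
        else:
            n_avoid += 1
            ok_avoid += correct
        if keep_trials:
            trials.append({"should_eat": should_eat, "ate": ate,
                           "steps": state.step_count})
    return EvalReport(
        n_should_eat=n_eat,
        n_should_avoid=n_avoid,
        pct_correct_approach=100.0 * ok_eat / n_eat if n_eat else float("nan"),
        pct_correct_avoid=100.0 * ok_avoid / n_avoid if n_avoid else float("nan"),
        trials=trials,
    )


def reward_curve(episode_rewards, optimal_rewards, bin_size: int = 100):
    """Mean agent reward and mean best-achievable reward per consecutive
    bin of episodes (only complete bins are reported).

    The oracle series fluctuates with the should-eat fraction of each
    bin — avoiding observed food caps the return at the accumulated
    step cost, while unobserved food is worth nearly +1000.
    """
    episode_rewards = np.asarray(episode_rewards, dtype=float)
    optimal_rewards = np.asarray(optimal_rewards, dtype=float)
    if episode_rewards.shape != optimal_rewards.shape:
        raise ValueError("series lengths differ")
    n_bins = episode_rewards.size // bin_size
    agent = episode_rewards[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    oracle = optimal_rewards[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    return agent, oracle


# ---------------------------------------------------------------------------
# Linear probing
# ---------------------------------------------------------------------------

@dataclass
class ProbeReport:
    """Validation accuracy of an LDA probe per architecture layer."""

    accuracy: dict[str, float]

    def __post_init__(self):
        missing = set(PROBE_LAYERS) - set(self.accuracy)
        if missing:
            raise ValueError(f"missing probe layers: {sorted(missing)}")

    @property
    def layers(self) -> tuple[str, ...]:
        return PROBE_LAYERS


def collect_activations(net: DuelingQNet, states: list[WorldState],
                        chunk: int = 1024):
    """Capture every probe layer's activations on first-time-step
    observations (zero hidden state), with the food-visibility label."""
    acts: dict[str, list[np.ndarray]] = {name: [] for name in PROBE_LAYERS}
    labels = np.array([s.food_observed for s in states], dtype=int)
    for i in range(0, len(states), chunk):
        batch = states[i:i + chunk]
        maps = np.stack([build_observation(s, net.vision_frame).maps()
                         for s in batch])
        orients = np.stack([build_observation(s, net.vision_frame).orientations()
                            for s in batch])
        out = net.layer_activations(maps, orients)
        for name in PROBE_LAYERS:
            acts[name].append(out[name])
    return {name: np.concatenate(v) for name, v in acts.items()}, labels


def save_activations(path: str, activations: dict[str, np.ndarray],
                     labels: np.ndarray) -> None:
    """Archive per-layer activation tables plus labels as .npz (keys:
    ``act/<layer>`` in the fixed probe-layer order, and ``labels``)."""
    np.savez_compressed(path, labels=np.asarray(labels),
                        **{f"act/{k}": np.asarray(v)
                           for k, v in activations.items()})


def load_activations(path: str):
    with np.load(path) as data:
        acts = {k[4:]: data[k] for k in data.files if k.startswith("act/")}
        return acts, data["labels"]


def eval_report_to_json(report: EvalReport, path: str) -> None:
    import json
    payload = {
        "n_should_eat": report.n_should_eat,
        "n_should_avoid": report.n_should_avoid,
        "pct_correct_approach": report.pct_correct_approach,
        "pct_correct_avoid": report.pct_correct_avoid,
        "trials": report.trials,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def reward_curve_to_csv(path: str, agent: np.ndarray, oracle: np.ndarray,
                        bin_size: int = 100) -> None:
    """Per-bin agent mean and best-achievable mean, one row per bin."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin", "episodes", "agent_mean_reward", "optimal_mean_reward"])
        for i, (a, o) in enumerate(zip(agent, oracle)):
            w.writerow([i, bin_size, a, o])


def _fit_lda(x_tr, y_tr, x_va, y_va) -> float:
    try:
        clf = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinear binary features
            clf.fit(x_tr, y_tr)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class covariance; using shrinkage LDA")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(x_tr, y_tr)
    return float(clf.score(x_va, y_va))


def linear_probe_layers(activations: dict[str, np.ndarray], labels: np.ndarray,
                        split_seed: int = 0, val_fraction: float = 0.2) -> ProbeReport:
    """Fit an LDA decoder of the visibility bit on each layer.

    Uses a seeded 80/20 split shared across layers; falls back to a
    shrinkage-regularized discriminant when the within-class covariance
    is singular (likely for binary input features).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("probe labels contain a single class")
    n = labels.shape[0]
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    va, tr = perm[:n_val], perm[n_val:]
    acc = {}
    for name in PROBE_LAYERS:
        x = np.asarray(activations[name], dtype=np.float64)
        acc[name] = _fit_lda(x[tr], labels[tr], x[va], labels[va])
    return ProbeReport(acc)
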