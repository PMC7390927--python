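"""Episode collection, trajectory replay and the Q-learning loop.

Training follows the deep recurrent Q-learning recipe: whole episodes
(padded to 100 steps, zero-padded tails masked out) are stored in a
1000-trajectory FIFO replay buffer; batches of 16 trajectories are
unrolled through the recurrent network from a zero hidden state; the
temporal-difference target for each valid step bootstraps from a slowly
moving target network (Polyak tau-averaging); gradients are clipped at
global norm 2 and applied with Adam at learning rate 0.001.  Exploration
is epsilon-greedy, annealed linearly from 1.0 to 0.1 over the first 75%
of environment steps.
"""

from __future__ import annotations

import copy
import csv
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .agent import (DuelingQNet, anneal_epsilon, epsilon_greedy_action,
                    soft_update)
from .encodings import (N_ACTIONS, action_to_world, build_observation,
                        observation_shapes)
from .env import (RewardSpec, ScenarioSampler, ScenarioSpec, WorldState,
                  optimal_episode_reward, step)

__all__ = [
    "Trajectory",
    "ReplayBuffer",
    "TrainConfig",
    "TrainingLog",
    "collect_episode",
    "sample_batch",
    "td_loss",
    "run_training",
]

MAX_T = 100


@dataclass
class Trajectory:
    """One padded episode.

    Maps/orientations are stored as uint8 (the observations are binary)
    and cast to float32 at batch time.  ``mask`` is 1 for real steps and
    0 for padding; at most one ``done`` flag is set, at the last valid
    step.
    """

    maps: np.ndarray        # (T, H, W, C) uint8
    orients: np.ndarray     # (T, n_orient) uint8
    actions: np.ndarray     # (T,) int8
    rewards: np.ndarray     # (T,) float32
    dones: np.ndarray       # (T,) bool
    mask: np.ndarray        # (T,) float32
    length: int
    initial_state: WorldState
    total_reward: float

    def __post_init__(self):
        assert self.maps.shape[0] == MAX_T, "trajectories are padded to 100 steps"


class ReplayBuffer:
    """FIFO ring buffer of whole trajectories, capacity 1000."""

    def __init__(self, capacity: int = 1000):
        self.capacity = capacity
        self._buf: deque[Trajectory] = deque(maxlen=capacity)

    def add(self, traj: Trajectory) -> None:
        self._buf.append(traj)

    def __len__(self) -> int:
        return len(self._buf)

    def __getitem__(self, i: int) -> Trajectory:
        return self._buf[i]


def sample_batch(buffer: ReplayBuffer, batch_size: int,
                 rng: np.random.Generator) -> list[Trajectory] | None:
    """Uniform sample of trajectories without replacement within the
    batch; returns None while the buffer is underfilled."""
    if len(buffer) < batch_size:
        return None
    idx = rng.choice(len(buffer), size=batch_size, replace=False)
    return [buffer[int(i)] for i in idx]


def collect_episode(net: DuelingQNet, sampler: ScenarioSampler,
                    action_frame: str, rewards: RewardSpec,
                    epsilon: float, rng: np.random.Generator,
                    initial_state: WorldState | None = None) -> Trajectory:
    """Roll out one episode with a fresh (zero) LSTM state.

    Actions are epsilon-greedy on the recurrent Q-values; the episode
    ends when the food is eaten or after ``rewards.max_steps`` steps,
    and the record is zero-padded to 100 steps.
    """
    init = initial_state if initial_state is not None else sampler.sample(rng)
    state = init
    (h_m, w_m, c_m), n_or = observation_shapes(net.vision_frame, net.grid_n)
    maps = np.zeros((MAX_T, h_m, w_m, c_m), dtype=np.uint8)
    orients = np.zeros((MAX_T, n_or), dtype=np.uint8)
    actions = np.zeros(MAX_T, dtype=np.int8)
    rews = np.zeros(MAX_T, dtype=np.float32)
    dones = np.zeros(MAX_T, dtype=bool)
    mask = np.zeros(MAX_T, dtype=np.float32)

    h, c = net.init_state(1)
    t = 0
    total = 0.0
    done = False
    while not done:
        obs = build_observation(state, net.vision_frame)
        m, o = obs.maps(), obs.orientations()
        q, h, c = net.forward_q(m[None], o[None], h, c)
        a = epsilon_greedy_action(q[0], epsilon, rng)
        disp, new_orient = action_to_world(a, action_frame,
                                           state.subordinate.orientation)
        outcome = step(state, disp, new_orient, rewards)
        maps[t], orients[t] = m, o
        actions[t] = a
        rews[t] = outcome.reward
        dones[t] = outcome.done
        mask[t] = 1.0
        total += outcome.reward
        state = outcome.next_state
        done = outcome.done
        t += 1
    return Trajectory(maps, orients, actions, rews, dones, mask, t,
                      initial_state=init, total_reward=total)


def td_loss(net: DuelingQNet, target_net: DuelingQNet,
            batch: list[Trajectory], gamma: float) -> float:
    """Masked TD(0) loss over a trajectory batch; accumulates gradients.

    Both networks are unrolled from zero hidden states over each full
    episode.  Per valid step, the target is ``r_t`` at termination and
    ``r_t + gamma * max_a Q(s_{t+1}, a; theta^-)`` otherwise; the loss
    is the squared error averaged over valid steps only, padded steps
    contributing exactly zero.
    """
    batch = sorted(batch, key=lambda tr: tr.length, reverse=True)
    bsz = len(batch)
    t_max = max(tr.length for tr in batch)
    lengths = np.array([tr.length for tr in batch], dtype=np.int64)
    maps = np.stack([tr.maps[:t_max] for tr in batch]).astype(nn.DTYPE)
    orients = np.stack([tr.orients[:t_max] for tr in batch]).astype(nn.DTYPE)
    actions = np.stack([tr.actions[:t_max] for tr in batch]).astype(np.int64)
    rewards = np.stack([tr.rewards[:t_max] for tr in batch])
    dones = np.stack([tr.dones[:t_max] for tr in batch])
    mask = np.stack([tr.mask[:t_max] for tr in batch])

    n_valid = float(mask.sum())
    if n_valid == 0:
        net.zero_grad()
        return 0.0

    h0, c0 = net.init_state(bsz)
    q = net.forward_seq(maps, orients, h0, c0, lengths)   # (B,T,5)
    th0, tc0 = target_net.init_state(bsz)
    q_tgt = target_net.forward_seq(maps, orients, th0, tc0, lengths,
                                   need_grad=False)
    next_max = np.zeros((bsz, t_max), dtype=np.float64)
    if t_max > 1:
        next_max[:, :-1] = q_tgt[:, 1:, :].max(axis=2)
    targets = rewards + gamma * next_max * (~dones)
    b_idx, t_idx = np.meshgrid(np.arange(bsz), np.arange(t_max), indexing="ij")
    q_taken = q[b_idx, t_idx, actions]
    delta = (q_taken - targets) * mask
    loss = float((delta ** 2).sum() / n_valid)

    dq = np.zeros_like(q)
    dq[b_idx, t_idx, actions] = (2.0 * delta / n_valid).astype(nn.DTYPE)
    net.zero_grad()
    net.backward(dq)
    return loss


@dataclass
class TrainConfig:
    """Hyperparameters of the RL runs.

    Defaults follow the main protocol: 2e7 environment steps, Adam at
    0.001 with batches of 16 trajectories, gradient clip 2, replay
    capacity 1000, epsilon 1 -> 0.1 at 75% of steps.  The discount
    (0.99), soft-update rate tau (0.001, applied at every gradient
    step) and the one-update-per-episode cadence are this package's
    configurable choices.
    """

    vision_frame: str = "ego"
    action_frame: str = "ego"
    grid_n: int = 11
    spawn_n: int = 5
    total_steps: int = 20_000_000
    learning_rate: float = 0.001
    batch_size: int = 16
    gradient_clip: float = 2.0
    tau: float = 0.001
    gamma: float = 0.99
    buffer_capacity: int = 1000
    updates_per_episode: int = 1
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    epsilon_end_fraction: float = 0.75
    seed: int = 0
    rewards: RewardSpec = field(default_factory=RewardSpec)

    def __post_init__(self):
        if self.vision_frame not in ("ego", "allo") or self.action_frame not in ("ego", "allo"):
            raise ValueError("frames must be 'ego' or 'allo'")
        for name in ("total_steps", "learning_rate", "batch_size",
                     "gradient_clip", "tau", "gamma", "buffer_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingLog:
    """Append-only per-episode record plus step counters."""

    episode_reward: list[float] = field(default_factory=list)
    optimal_reward: list[float] = field(default_factory=list)
    epsilon: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    env_steps: int = 0
    grad_steps: int = 0

    def append(self, reward, optimal, eps, loss, gnorm):
        self.episode_reward.append(float(reward))
        self.optimal_reward.append(float(optimal))
        self.epsilon.append(float(eps))
        self.loss.append(float(loss))
        self.grad_norm.append(float(gnorm))

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["episode", "reward", "optimal_reward", "epsilon",
                        "loss", "grad_norm"])
            for i in range(len(self.episode_reward)):
                w.writerow([i, self.episode_reward[i], self.optimal_reward[i],
                            self.epsilon[i], self.loss[i], self.grad_norm[i]])


def run_training(config: TrainConfig,
                 scenario: ScenarioSpec | None = None,
                 checkpoint_path: str | None = None,
                 progress: bool = False):
    """Full RL loop for one visuomotor condition.

    Interleaves episode collection (with the annealed epsilon), replay
    insertion, TD updates with clipped Adam, and a soft target update
    after every gradient step.  Returns ``(net, log)`` and optionally
    writes a final checkpoint.
    """
    if scenario is None:
        scenario = ScenarioSpec.default(config.grid_n, config.spawn_n)
    sampler = ScenarioSampler(scenario)
    rng = np.random.default_rng(config.seed)
    net = DuelingQNet(config.vision_frame, config.grid_n,
                      seed=int(rng.integers(2 ** 31)))
    target = DuelingQNet(config.vision_frame, config.grid_n, seed=net.seed)
    target.load_parameters(copy.deepcopy(net.parameters()))
    target_params = target.parameters()
    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    buffer = ReplayBuffer(config.buffer_capacity)
    log = TrainingLog()

    while log.env_steps < config.total_steps:
        eps = anneal_epsilon(log.env_steps, config.total_steps,
                             config.epsilon_start, config.epsilon_end,
                             config.epsilon_end_fraction)
        init = sampler.sample(rng)
        traj = collect_episode(net, sampler, config.action_frame,
                               config.rewards, eps, rng, initial_state=init)
        buffer.add(traj)
        log.env_steps += traj.length

        loss_val, gnorm = float("nan"), float("nan")
        batch = None
        for _ in range(config.updates_per_episode):
            batch = sample_batch(buffer, config.batch_size, rng)
            if batch is None:
                break
            loss_val = td_loss(net, target, batch, config.gamma)
            grads = net.gradients()
            pre = nn.clip_global_norm(grads, config.gradient_clip)
            gnorm = min(pre, config.gradient_clip)  # post-clip norm
            opt.step(net.parameters(), grads)
            soft_update(net.parameters(), target_params, config.tau)
            log.grad_steps += 1
        log.append(traj.total_reward, optimal_episode_reward(
            traj.initial_state, config.rewards), eps, loss_val, gnorm)
        if progress and len(log.episode_reward) % 100 == 0:
            recent = np.mean(log.episode_reward[-100:])
            print(f"episodes={len(log.episode_reward)} steps={log.env_steps} "
                  f"eps={eps:.3f} mean_reward(100)={recent:.1f}")

    if checkpoint_path is not None:
        from .agent import save_checkpoint
        save_checkpoint(checkpoint_path, net, target_params, opt,
                        meta={"config": {k: v for k, v in vars(config).items()
                                         if not isinstance(v, RewardSpec)}})
    return net, log
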