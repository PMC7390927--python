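"""Supervised visibility classification: can a feed-forward readout of a
single initial observation tell whether the Dominant sees the food?

This isolates the perceptual part of the perspective-taking task from
memory and navigation.  The dataset is every enumerable initial
configuration of a scenario, labelled with the ground-truth visibility
bit; the model is the Q-network architecture with the LSTM removed and a
single sigmoid output, trained with binary cross-entropy (Adam, learning
rate 0.001, batch 64, 80/20 train/validation split), and accuracies are
averaged over 20 random weight initializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .agent import DuelingQNet
from .encodings import build_observation, observation_shapes
from .env import ScenarioSpec, enumerate_initial_configs

__all__ = [
    "VisibilityDataset",
    "SupervisedConfig",
    "AccuracyCurve",
    "VisibilityNet",
    "build_visibility_dataset",
    "train_visibility_classifier",
]


@dataclass
class VisibilityDataset:
    """All initial configurations of a scenario in one frame, with the
    food-visibility label and a deterministic 80/20 split."""

    maps: np.ndarray       # (N, H, W, C) uint8
    orients: np.ndarray    # (N, n_orient) uint8
    labels: np.ndarray     # (N,) uint8
    train_idx: np.ndarray
    val_idx: np.ndarray
    vision_frame: str
    grid_n: int

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclass
class SupervisedConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 0.001
    val_fraction: float = 0.2
    n_inits: int = 20
    seed: int = 0


@dataclass
class AccuracyCurve:
    """Per-epoch validation accuracy: one row per initialization, plus
    the across-initialization mean and standard error."""

    per_init: np.ndarray   # (n_inits, epochs)

    @property
    def mean(self) -> np.ndarray:
        return self.per_init.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.per_init.shape[0]
        if n == 1:
            return np.zeros(self.per_init.shape[1])
        return self.per_init.std(axis=0, ddof=1) / np.sqrt(n)

    def to_csv(self, path: str) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "mean_val_accuracy", "sem"])
            for e, (m, s) in enumerate(zip(self.mean, self.sem), start=1):
                w.writerow([e, m, s])


def build_visibility_dataset(scenario: ScenarioSpec, vision_frame: str,
                             split_seed: int = 0,
                             val_fraction: float = 0.2) -> VisibilityDataset:
    """Encode every enumerated initial configuration and attach labels.

    The label is the world-geometry fact ``food_observed_by_dominant``,
    so class balance is identical between visual frames; only the input
    encoding differs.
    """
    states = enumerate_initial_configs(scenario)
    n = len(states)
    (h, w, c), n_or = observation_shapes(vision_frame, scenario.grid.n)
    maps = np.empty((n, h, w, c), dtype=np.uint8)
    orients = np.empty((n, n_or), dtype=np.uint8)
    labels = np.empty(n, dtype=np.uint8)
    for i, st in enumerate(states):
        obs = build_observation(st, vision_frame)
        maps[i] = obs.maps()
        orients[i] = obs.orientations()
        labels[i] = st.food_observed
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    return VisibilityDataset(maps, orients, labels,
                             train_idx=np.sort(perm[n_val:]),
                             val_idx=np.sort(perm[:n_val]),
                             vision_frame=vision_frame,
                             grid_n=scenario.grid.n)


class VisibilityNet:
    """The Q-network trunk without the LSTM, ending in one sigmoid unit.

    conv(6, 3x3) -> merge with orientations -> FC_1(32) -> FC_2(32)
    -> FC_3(32) -> sigmoid readout; hidden layers ReLU.
    """

    def __init__(self, vision_frame: str, grid_n: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        (h, w, c), n_orient = observation_shapes(vision_frame, grid_n)
        k, f = DuelingQNet.KERNEL, DuelingQNet.N_FILTERS
        u = DuelingQNet.FC_UNITS
        self.flat = (h - k + 1) * (w - k + 1) * f
        self.conv = nn.Conv2D(c, f, k, rng, input_grad=False)
        self.fc1 = nn.Dense(self.flat + n_orient, u, rng)
        self.fc2 = nn.Dense(u, u, rng)
        self.fc3 = nn.Dense(u, u, rng)
        self.out = nn.Dense(u, 1, rng)
        self.layers = {"conv": self.conv, "fc1": self.fc1, "fc2": self.fc2,
                       "fc3": self.fc3, "out": self.out}

    def parameters(self):
        return {f"{ln}/{k}": v for ln, layer in self.layers.items()
                for k, v in layer.params.items()}

    def gradients(self):
        return {f"{ln}/{k}": v for ln, layer in self.layers.items()
                for k, v in layer.grads.items()}

    def zero_grad(self):
        for layer in self.layers.values():
            layer.zero_grad()

    def forward(self, maps: np.ndarray, orients: np.ndarray) -> np.ndarray:
        """Probability that the Dominant sees the food; shape (B,)."""
        self._y1 = nn.relu(self.conv.forward(maps))
        merge = np.concatenate([self._y1.reshape(maps.shape[0], -1), orients], axis=1)
        self._y2 = nn.relu(self.fc1.forward(merge))
        self._y3 = nn.relu(self.fc2.forward(self._y2))
        self._y4 = nn.relu(self.fc3.forward(self._y3))
        z = self.out.forward(self._y4)[:, 0]
        return nn.sigmoid(z)

    def backward(self, dz: np.ndarray) -> None:
        """Backward from dL/dz of the pre-sigmoid logit, shape (B,)."""
        d4 = self.out.backward(dz[:, None].astype(nn.DTYPE))
        d4 = nn.relu_backward(d4, self._y4)
        d3 = nn.relu_backward(self.fc3.backward(d4), self._y3)
        d2 = nn.relu_backward(self.fc2.backward(d3), self._y2)
        dmerge = self.fc1.backward(d2)
        dconv = nn.relu_backward(
            dmerge[:, : self.flat].reshape(self._y1.shape), self._y1)
        self.conv.backward(dconv)


def _accuracy(net: VisibilityNet, maps: np.ndarray, orients: np.ndarray,
              labels: np.ndarray, chunk: int = 4096) -> float:
    hits = 0
    for i in range(0, maps.shape[0], chunk):
        p = net.forward(maps[i:i + chunk], orients[i:i + chunk])
        hits += int(((p >= 0.5) == labels[i:i + chunk]).sum())
    return hits / maps.shape[0]


def train_visibility_classifier(dataset: VisibilityDataset,
                                config: SupervisedConfig) -> AccuracyCurve:
    """Train the LSTM-free classifier over several weight seeds.

    Binary cross-entropy on the visibility bit; the logit gradient is
    the usual ``p - y`` residual.  Returns the per-epoch validation
    accuracy for each initialization.
    """
    labels = dataset.labels
    if labels.min() == labels.max():
        raise ValueError("dataset contains a single class; nothing to learn")
    f_maps = dataset.maps.astype(nn.DTYPE)
    f_or = dataset.orients.astype(nn.DTYPE)
    y = labels.astype(nn.DTYPE)
    tr, va = dataset.train_idx, dataset.val_idx
    tr_maps, tr_or, tr_y = f_maps[tr], f_or[tr], y[tr]
    va_maps, va_or, va_y = f_maps[va], f_or[va], labels[va]

    master = np.random.default_rng(config.seed)
    init_seeds = master.integers(2 ** 31, size=config.n_inits)
    curves = np.zeros((config.n_inits, config.epochs))
    for i, s in enumerate(init_seeds):
        net = VisibilityNet(dataset.vision_frame, dataset.grid_n, seed=int(s))
        opt = nn.Adam(net.parameters(), lr=config.learning_rate)
        rng = np.random.default_rng(int(s) + 1)
        n_tr = tr_maps.shape[0]
        for epoch in range(config.epochs):
            order = rng.permutation(n_tr)
            for j in range(0, n_tr, config.batch_size):
                idx = order[j:j + config.batch_size]
                p = net.forward(tr_maps[idx], tr_or[idx])
                dz = (p - tr_y[idx]) / idx.shape[0]
                net.zero_grad()
                net.backward(dz)
                opt.step(net.parameters(), net.gradients())
            curves[i, epoch] = _accuracy(net, va_maps, va_or, va_y)
    return AccuracyCurve(curves)
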