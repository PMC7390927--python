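"""Dueling recurrent Q-network and policy primitives.

Architecture: one 3x3 valid convolution with 6 filters over the binary
observation maps; the flattened features are concatenated with the
orientation one-hot vectors ("merge"), passed through two 32-unit fully
connected layers, a 128-cell LSTM, a shared 32-unit layer (FC_3), and
two linear heads — a scalar state value V and 5 action advantages A —
recombined as

    Q(s, a) = V(s) + (A(s, a) - max_a' A(s, a')),

so that max_a Q = V exactly.  The egocentric variant takes 11 x 21 maps
and only the Dominant's relative orientation; the allocentric variant
takes n x n maps and both agents' orientations.  Hidden layers use ReLU.
"""

from __future__ import annotations

import json

import numpy as np

from . import nn
from .encodings import N_ACTIONS, observation_shapes

__all__ = [
    "DuelingQNet",
    "dueling_aggregate",
    "epsilon_greedy_action",
    "soft_update",
    "anneal_epsilon",
    "save_checkpoint",
    "load_checkpoint",
]

PROBE_LAYERS = ("input", "flatten", "merge", "FC_1", "FC_2", "LSTM", "FC_3", "output")


def dueling_aggregate(v, a) -> np.ndarray:
    """Q[a] = V + A[a] - max(A); the max-subtraction identity makes the
    greedy action's Q equal V."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("advantage vector must be non-empty")
    return np.asarray(v, dtype=float) + (a - a.max(axis=-1, keepdims=True))


def epsilon_greedy_action(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Random action with probability epsilon, else argmax of Q (ties
    resolved to the lowest action index)."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if rng.random() < epsilon:
        return int(rng.integers(len(q)))
    return int(np.argmax(q))


def soft_update(params: dict, target: dict, tau: float) -> None:
    """In-place Polyak averaging of the target parameters:
    target <- tau * online + (1 - tau) * target."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if params.keys() != target.keys():
        raise ValueError("parameter sets do not match")
    for k in params:
        if params[k].shape != target[k].shape:
            raise ValueError(f"shape mismatch for {k}")
        target[k] *= 1.0 - tau
        target[k] += tau * params[k]


def anneal_epsilon(step: int, total_steps: int, start: float = 1.0,
                   end: float = 0.1, end_fraction: float = 0.75) -> float:
    """Linear exploration schedule: from ``start`` at step 0 down to
    ``end`` at ``end_fraction`` of the run, constant afterwards."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    knee = end_fraction * total_steps
    if step >= knee:
        return end
    return start + (end - start) * (step / knee)


class DuelingQNet:
    """The Q-network; owns its layers, exposes flat parameter dicts.

    Parameters
    ----------
    vision_frame : {"allo", "ego"}
        Chooses input map shape and orientation-vector width.
    grid_n : int
        World side length (13 allocentric / 11 egocentric by default).
    seed : int
        Weight-initialization seed (Glorot-uniform kernels, orthogonal
        recurrent kernel); recorded on the instance.
    """

    N_FILTERS = 6
    KERNEL = 3
    FC_UNITS = 32
    LSTM_CELLS = 128

    def __init__(self, vision_frame: str, grid_n: int, seed: int = 0):
        self.vision_frame = vision_frame
        self.grid_n = grid_n
        self.seed = seed
        rng = np.random.default_rng(seed)
        (h, w, c), n_orient = observation_shapes(vision_frame, grid_n)
        self.map_shape = (h, w, c)
        self.n_orient = n_orient
        flat = (h - self.KERNEL + 1) * (w - self.KERNEL + 1) * self.N_FILTERS
        self.flat = flat
        self.conv = nn.Conv2D(c, self.N_FILTERS, self.KERNEL, rng, input_grad=False)
        self.fc1 = nn.Dense(flat + n_orient, self.FC_UNITS, rng)
        self.fc2 = nn.Dense(self.FC_UNITS, self.FC_UNITS, rng)
        self.lstm = nn.LSTM(self.FC_UNITS, self.LSTM_CELLS, rng)
        self.fc3 = nn.Dense(self.LSTM_CELLS, self.FC_UNITS, rng)
        self.head_v = nn.Dense(self.FC_UNITS, 1, rng)
        self.head_a = nn.Dense(self.FC_UNITS, N_ACTIONS, rng)
        self.layers = {
            "conv": self.conv, "fc1": self.fc1, "fc2": self.fc2,
            "lstm": self.lstm, "fc3": self.fc3,
            "head_v": self.head_v, "head_a": self.head_a,
        }
        self._cache = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}/{k}": v for ln, layer in self.layers.items()
                for k, v in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}/{k}": v for ln, layer in self.layers.items()
                for k, v in layer.grads.items()}

    def load_parameters(self, flat: dict[str, np.ndarray]) -> None:
        for ln, layer in self.layers.items():
            for k in layer.params:
                layer.params[k][...] = flat[f"{ln}/{k}"]

    def zero_grad(self) -> None:
        for layer in self.layers.values():
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.parameters().values())

    def init_state(self, batch: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Fresh all-zero LSTM state, reset at every episode start."""
        return self.lstm.init_state(batch)

    # -- forward / backward -------------------------------------------------

    def _trunk(self, maps: np.ndarray, orients: np.ndarray):
        """Shared pre-LSTM stack on a flat batch; returns FC_2 output."""
        y1 = nn.relu(self.conv.forward(maps))
        flat = y1.reshape(maps.shape[0], -1)
        merge = np.concatenate([flat, orients], axis=1)
        y2 = nn.relu(self.fc1.forward(merge))
        y3 = nn.relu(self.fc2.forward(y2))
        return y1, merge, y2, y3

    def forward_seq(self, maps: np.ndarray, orients: np.ndarray,
                    h0: np.ndarray, c0: np.ndarray,
                    lengths: np.ndarray | None = None,
                    need_grad: bool = True) -> np.ndarray:
        """Q-values over full sequences.

        maps: (B, T, H, W, C) float32; orients: (B, T, n_orient).
        ``lengths`` (sorted descending) activates packed processing:
        only valid steps pass through the trunk and heads, and the LSTM
        drops finished sequences from its batch; Q at padded steps is
        zero.  Returns (B, T, 5) and caches for :meth:`backward`.
        """
        bsz, t_len = maps.shape[:2]
        if lengths is None:
            valid = np.ones((bsz, t_len), dtype=bool)
        else:
            valid = np.arange(t_len)[None, :] < np.asarray(lengths)[:, None]
        flat_maps = maps[valid]
        flat_or = orients[valid]
        y1, merge, y2, y3 = self._trunk(flat_maps, flat_or)
        x_seq = np.zeros((bsz, t_len, y3.shape[1]), dtype=nn.DTYPE)
        x_seq[valid] = y3
        hs = self.lstm.forward(x_seq, h0, c0, lengths, need_grad=need_grad)
        y4 = nn.relu(self.fc3.forward(hs[valid]))
        v = self.head_v.forward(y4)
        a = self.head_a.forward(y4)
        amax_idx = np.argmax(a, axis=1)
        q_flat = v + (a - a[np.arange(a.shape[0]), amax_idx][:, None])
        q = np.zeros((bsz, t_len, N_ACTIONS), dtype=q_flat.dtype)
        q[valid] = q_flat
        self._cache = (valid, y1, y2, y3, y4, amax_idx)
        return q

    def backward(self, dq: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dQ of shape (B, T, 5)."""
        valid, y1, y2, y3, y4, amax_idx = self._cache
        bsz, t_len = valid.shape
        dq2 = dq[valid].astype(nn.DTYPE)
        dv = dq2.sum(axis=1, keepdims=True)
        da = dq2.copy()
        da[np.arange(da.shape[0]), amax_idx] -= dq2.sum(axis=1)
        d4 = self.head_v.backward(dv) + self.head_a.backward(da)
        d4 = nn.relu_backward(d4, y4)
        dh = np.zeros((bsz, t_len, self.LSTM_CELLS), dtype=nn.DTYPE)
        dh[valid] = self.fc3.backward(d4)
        d3 = self.lstm.backward(dh)[valid]
        d3 = nn.relu_backward(d3, y3)
        d2 = nn.relu_backward(self.fc2.backward(d3), y2)
        dmerge = self.fc1.backward(d2)
        dflat = dmerge[:, : self.flat]
        dconv = nn.relu_backward(
            dflat.reshape(y1.shape), y1)
        self.conv.backward(dconv)

    def forward_q(self, maps: np.ndarray, orients: np.ndarray,
                  h: np.ndarray, c: np.ndarray):
        """Single-step inference for acting.

        maps: (B, H, W, C); orients: (B, n_orient); (h, c): LSTM state.
        Returns (Q (B, 5), h', c').
        """
        _, _, _, y3 = self._trunk(
            maps.astype(nn.DTYPE), orients.astype(nn.DTYPE))
        h2, c2 = self.lstm.step(y3, h, c)
        y4 = nn.relu(self.fc3.forward(h2))
        v = self.head_v.forward(y4)
        a = self.head_a.forward(y4)
        q = v + (a - a.max(axis=1, keepdims=True))
        return q, h2, c2

    def layer_activations(self, maps: np.ndarray, orients: np.ndarray) -> dict[str, np.ndarray]:
        """First-time-step activations at every probe layer.

        Keys: input (flattened raw observation incl. orientations),
        flatten (post-conv, pre-merge), merge, FC_1, FC_2, LSTM, FC_3,
        output (the 5 Q-values).  LSTM starts from a zero state.
        """
        maps = maps.astype(nn.DTYPE)
        orients = orients.astype(nn.DTYPE)
        bsz = maps.shape[0]
        y1, merge, y2, y3 = self._trunk(maps, orients)
        h0, c0 = self.lstm.init_state(bsz)
        h, _ = self.lstm.step(y3, h0, c0)
        y4 = nn.relu(self.fc3.forward(h))
        v = self.head_v.forward(y4)
        a = self.head_a.forward(y4)
        q = v + (a - a.max(axis=1, keepdims=True))
        return {
            "input": np.concatenate([maps.reshape(bsz, -1), orients], axis=1),
            "flatten": y1.reshape(bsz, -1),
            "merge": merge,
            "FC_1": y2,
            "FC_2": y3,
            "LSTM": h,
            "FC_3": y4,
            "output": q,
        }


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, net: DuelingQNet,
                    target_params: dict[str, np.ndarray] | None = None,
                    optimizer: "nn.Adam | None" = None,
                    rng_state: dict | None = None,
                    meta: dict | None = None) -> None:
    """Serialize network weights (and optionally target weights, Adam
    state and RNG state) into a single .npz archive.

    Reloading reproduces :meth:`DuelingQNet.forward_q` bit-for-bit.
    """
    arrays: dict[str, np.ndarray] = {}
    for k, v in net.parameters().items():
        arrays["p/" + k] = v
    if target_params is not None:
        for k, v in target_params.items():
            arrays["t/" + k] = v
    if optimizer is not None:
        state = optimizer.state_dict()
        for k, v in state["m"].items():
            arrays["am/" + k] = v
        for k, v in state["v"].items():
            arrays["av/" + k] = v
        arrays["a_t"] = np.array([state["t"]])
        arrays["a_lr"] = np.array([state["lr"]])
    header = {
        "vision_frame": net.vision_frame,
        "grid_n": net.grid_n,
        "seed": net.seed,
        "meta": meta or {},
    }
    if rng_state is not None:
        header["rng_state"] = _jsonable(rng_state)
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return {"__nd__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _unjsonable(obj):
    if isinstance(obj, dict):
        if "__nd__" in obj:
            return np.array(obj["__nd__"], dtype=obj["dtype"])
        return {k: _unjsonable(v) for k, v in obj.items()}
    return obj


def load_checkpoint(path: str):
    """Rebuild the network (and target weights / Adam / RNG state if
    present).  Returns (net, target_params, adam_state, rng_state, meta)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        net = DuelingQNet(header["vision_frame"], header["grid_n"],
                          seed=header["seed"])
        net.load_parameters(
            {k[2:]: data[k] for k in data.files if k.startswith("p/")})
        target = {k[2:]: data[k].copy() for k in data.files if k.startswith("t/")} or None
        adam_state = None
        if "a_t" in data.files:
            adam_state = {
                "t": int(data["a_t"][0]),
                "lr": float(data["a_lr"][0]),
                "m": {k[3:]: data[k].copy() for k in data.files if k.startswith("am/")},
                "v": {k[3:]: data[k].copy() for k in data.files if k.startswith("av/")},
            }
        rng_state = _unjsonable(header.get("rng_state"))
    return net, target, adam_state, rng_state, header.get("meta", {})
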