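"""Minimal NumPy neural-network layers with hand-written gradients.

The package implements its networks directly on NumPy: a valid 2-D
convolution, dense layers, an LSTM with full backpropagation through
time, and an Adam optimizer with global-norm gradient clipping.  Layers
cache what their backward pass needs; parameters and gradients live in
plain dicts so that soft target updates and checkpointing are trivial.

All backward passes are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "glorot_uniform",
    "orthogonal",
    "Dense",
    "Conv2D",
    "LSTM",
    "relu",
    "relu_backward",
    "sigmoid",
    "Adam",
    "clip_global_norm",
    "global_norm",
]

DTYPE = np.float32


def glorot_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    if len(shape) > 2:  # conv kernel (kh, kw, cin, cout)
        receptive = int(np.prod(shape[:-2]))
        fan_in = receptive * shape[-2]
        fan_out = receptive * shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def orthogonal(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix sign ambiguity for determinism
    if rows < cols:
        q = q.T
    return q[:rows, :cols].astype(DTYPE, order="C")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping keeps exp() in range; exact to float precision for |x| < 50
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50.0, 50.0)))


class Layer:
    """Base: parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": glorot_uniform((n_in, n_out), rng),
            "b": np.zeros(n_out, dtype=DTYPE),
        }
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Conv2D(Layer):
    """Single 'valid' convolution, stride 1, NHWC layout, im2col based."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 input_grad: bool = True):
        super().__init__()
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.input_grad = input_grad
        self.params = {
            "W": glorot_uniform((kernel, kernel, c_in, c_out), rng),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self._cols = None
        self._x_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[-1] != self.c_in:
            raise ValueError(f"expected (B,H,W,{self.c_in}), got {x.shape}")
        k = self.kernel
        b, h, w, c = x.shape
        oh, ow = h - k + 1, w - k + 1
        # im2col via k*k contiguous block copies (fast; a strided-view
        # gather is several times slower for overlapping windows)
        cols4 = np.empty((b, oh, ow, k * k * c), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols4[..., (i * k + j) * c:(i * k + j + 1) * c] = \
                    x[:, i:i + oh, j:j + ow, :]
        cols = cols4.reshape(b * oh * ow, k * k * c)
        self._cols = cols
        self._x_shape = x.shape
        wmat = self.params["W"].reshape(k * k * c, self.c_out)
        out = cols @ wmat + self.params["b"]
        return out.reshape(b, oh, ow, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.kernel
        b, h, w, c = self._x_shape
        oh, ow = h - k + 1, w - k + 1
        dy2 = dy.reshape(b * oh * ow, self.c_out)
        wmat = self.params["W"].reshape(k * k * c, self.c_out)
        self.grads["W"] += (self._cols.T @ dy2).reshape(self.params["W"].shape)
        self.grads["b"] += dy2.sum(axis=0)
        if not self.input_grad:  # first-layer convs never need dL/dx
            return None
        dcols = (dy2 @ wmat.T).reshape(b, oh, ow, k, k, c)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        for i in range(k):  # col2im scatter-add, 9 vectorized adds for k=3
            for j in range(k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


@njit(cache=True, fastmath=True)
def _lstm_forward_kernel(x_seq, W, U, b, h0, c0, lens, gates, tcs, cs, hs):
    """Sequence forward in (T, B, ...) layout; fills the cache arrays.
    gates holds post-activation (i, f, g, o); tcs holds tanh(c).
    ``lens`` (descending) lets the active batch shrink as shorter
    sequences end; outputs beyond a sequence's length stay zero."""
    t_len, bsz, _ = x_seq.shape
    nh = h0.shape[1]
    h = h0.copy()
    c = c0.copy()
    for t in range(t_len):
        active = 0
        for bi in range(bsz):
            if lens[bi] > t:
                active += 1
        if active == 0:
            break
        z = x_seq[t, :active] @ W + h[:active] @ U
        for bi in range(active):
            for j in range(nh):
                i_g = 1.0 / (1.0 + np.exp(-(z[bi, j] + b[j])))
                f_g = 1.0 / (1.0 + np.exp(-(z[bi, nh + j] + b[nh + j])))
                g_g = np.tanh(z[bi, 2 * nh + j] + b[2 * nh + j])
                o_g = 1.0 / (1.0 + np.exp(-(z[bi, 3 * nh + j] + b[3 * nh + j])))
                cc = f_g * c[bi, j] + i_g * g_g
                tc = np.tanh(cc)
                gates[t, bi, j] = i_g
                gates[t, bi, nh + j] = f_g
                gates[t, bi, 2 * nh + j] = g_g
                gates[t, bi, 3 * nh + j] = o_g
                c[bi, j] = cc
                cs[t, bi, j] = cc
                tcs[t, bi, j] = tc
                h[bi, j] = o_g * tc
                hs[t, bi, j] = h[bi, j]


@njit(cache=True, fastmath=True)
def _lstm_infer_kernel(x_seq, W, U, b, h0, c0, lens, hs):
    """Forward without caches, for target-network evaluation."""
    t_len, bsz, _ = x_seq.shape
    nh = h0.shape[1]
    h = h0.copy()
    c = c0.copy()
    for t in range(t_len):
        active = 0
        for bi in range(bsz):
            if lens[bi] > t:
                active += 1
        if active == 0:
            break
        z = x_seq[t, :active] @ W + h[:active] @ U
        for bi in range(active):
            for j in range(nh):
                i_g = 1.0 / (1.0 + np.exp(-(z[bi, j] + b[j])))
                f_g = 1.0 / (1.0 + np.exp(-(z[bi, nh + j] + b[nh + j])))
                g_g = np.tanh(z[bi, 2 * nh + j] + b[2 * nh + j])
                o_g = 1.0 / (1.0 + np.exp(-(z[bi, 3 * nh + j] + b[3 * nh + j])))
                cc = f_g * c[bi, j] + i_g * g_g
                c[bi, j] = cc
                h[bi, j] = o_g * np.tanh(cc)
                hs[t, bi, j] = h[bi, j]


@njit(cache=True, fastmath=True)
def _lstm_backward_kernel(dh_seq, x_seq, hs, gates, tcs, cs, c0, h0, lens,
                          W, U, dW, dU, db, dx_seq):
    """BPTT in (T, B, ...) layout; accumulates parameter gradients.
    Rows whose sequence ended before step t carry no adjoint there."""
    t_len, bsz, nh = dh_seq.shape
    dh_next = np.zeros((bsz, nh), dtype=dh_seq.dtype)
    dc_next = np.zeros((bsz, nh), dtype=dh_seq.dtype)
    for t in range(t_len - 1, -1, -1):
        active = 0
        for bi in range(bsz):
            if lens[bi] > t:
                active += 1
        if active == 0:
            continue
        dz = np.empty((active, 4 * nh), dtype=dh_seq.dtype)
        for bi in range(active):
            for j in range(nh):
                i_g = gates[t, bi, j]
                f_g = gates[t, bi, nh + j]
                g_g = gates[t, bi, 2 * nh + j]
                o_g = gates[t, bi, 3 * nh + j]
                tc = tcs[t, bi, j]
                c_prev = cs[t - 1, bi, j] if t > 0 else c0[bi, j]
                dh = dh_seq[t, bi, j] + dh_next[bi, j]
                dc = dc_next[bi, j] + dh * o_g * (1.0 - tc * tc)
                dz[bi, j] = dc * g_g * i_g * (1.0 - i_g)
                dz[bi, nh + j] = dc * c_prev * f_g * (1.0 - f_g)
                dz[bi, 2 * nh + j] = dc * i_g * (1.0 - g_g * g_g)
                dz[bi, 3 * nh + j] = dh * tc * o_g * (1.0 - o_g)
                dc_next[bi, j] = dc * f_g
        h_prev = hs[t - 1, :active] if t > 0 else h0[:active]
        dW += x_seq[t, :active].T @ dz
        dU += h_prev.T @ dz
        for j in range(4 * nh):
            s = 0.0
            for bi in range(active):
                s += dz[bi, j]
            db[j] += s
        dx_seq[t, :active] = dz @ W.T
        dh_next[:active] = dz @ U.T


class LSTM(Layer):
    """Standard LSTM (gate order i, f, g, o) with BPTT.

    Kernel is Glorot-uniform, recurrent kernel orthogonal and the forget
    gate bias starts at 1 — the common recurrent-network defaults.  The
    sequence unroll and backpropagation-through-time loops are
    numba-compiled; the single-step path used while acting stays in
    plain NumPy.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        b = np.zeros(4 * n_hidden, dtype=DTYPE)
        b[n_hidden:2 * n_hidden] = 1.0
        self.params = {
            "W": glorot_uniform((n_in, 4 * n_hidden), rng),
            "U": orthogonal((n_hidden, 4 * n_hidden), rng)
            if n_hidden > 0 else np.zeros((0, 0), DTYPE),
            "b": b,
        }
        self._cache = None

    def init_state(self, batch: int) -> tuple[np.ndarray, np.ndarray]:
        z = np.zeros((batch, self.n_hidden), dtype=DTYPE)
        return z, z.copy()

    def _gates(self, x, h_prev, c_prev):
        nh = self.n_hidden
        z = x @ self.params["W"] + h_prev @ self.params["U"] + self.params["b"]
        i = sigmoid(z[:, :nh])
        f = sigmoid(z[:, nh:2 * nh])
        g = np.tanh(z[:, 2 * nh:3 * nh])
        o = sigmoid(z[:, 3 * nh:])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, c, (i, f, g, o, tc)

    def step(self, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        """Single inference step (no caching for backward)."""
        h2, c2, _ = self._gates(x, h, c)
        return h2, c2

    def forward(self, x_seq: np.ndarray, h0: np.ndarray, c0: np.ndarray,
                lengths: np.ndarray | None = None,
                need_grad: bool = True) -> np.ndarray:
        """Unrolled forward over (B, T, n_in); returns (B, T, n_hidden).

        ``lengths`` (one per sequence, sorted descending) lets shorter
        sequences drop out of the batch early; their outputs past the
        end are zero.  ``need_grad=False`` skips the BPTT caches
        (target-network evaluation).
        """
        bsz, t_len, _ = x_seq.shape
        if lengths is None:
            lengths = np.full(bsz, t_len, dtype=np.int64)
        else:
            lengths = np.asarray(lengths, dtype=np.int64)
            if np.any(np.diff(lengths) > 0):
                raise ValueError("lengths must be sorted descending")
        dt = self.params["W"].dtype
        xt = np.ascontiguousarray(x_seq.transpose(1, 0, 2), dtype=dt)
        if not need_grad:
            hs = np.zeros((t_len, bsz, self.n_hidden), dtype=dt)
            _lstm_infer_kernel(xt, self.params["W"], self.params["U"],
                               self.params["b"],
                               np.ascontiguousarray(h0, dtype=dt),
                               np.ascontiguousarray(c0, dtype=dt),
                               lengths, hs)
            return np.ascontiguousarray(hs.transpose(1, 0, 2))
        gates = np.zeros((t_len, bsz, 4 * self.n_hidden), dtype=dt)
        tcs = np.zeros((t_len, bsz, self.n_hidden), dtype=dt)
        cs = np.zeros((t_len, bsz, self.n_hidden), dtype=dt)
        hs = np.zeros((t_len, bsz, self.n_hidden), dtype=dt)
        h0 = np.ascontiguousarray(h0, dtype=dt)
        c0 = np.ascontiguousarray(c0, dtype=dt)
        _lstm_forward_kernel(xt, self.params["W"], self.params["U"],
                             self.params["b"], h0, c0, lengths,
                             gates, tcs, cs, hs)
        self._cache = (xt, h0, c0, lengths, gates, tcs, cs, hs)
        return np.ascontiguousarray(hs.transpose(1, 0, 2))

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        xt, h0, c0, lengths, gates, tcs, cs, hs = self._cache
        dt = self.params["W"].dtype
        dh_t = np.ascontiguousarray(dh_seq.transpose(1, 0, 2), dtype=dt)
        dx_t = np.zeros_like(xt)
        dW = np.zeros_like(self.params["W"])
        dU = np.zeros_like(self.params["U"])
        db = np.zeros_like(self.params["b"])
        _lstm_backward_kernel(dh_t, xt, hs, gates, tcs, cs, c0, h0, lengths,
                              self.params["W"], self.params["U"],
                              dW, dU, db, dx_t)
        self.grads["W"] += dW
        self.grads["U"] += dU
        self.grads["b"] += db
        return np.ascontiguousarray(dx_t.transpose(1, 0, 2))


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def global_norm(grads: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                             for g in grads.values())))


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``.
    Returns the pre-clip norm."""
    norm = global_norm(grads)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for g in grads.values():
            g *= scale
    return norm


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v) for k, v in state["v"].items()}
        self.lr = float(state["lr"])
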