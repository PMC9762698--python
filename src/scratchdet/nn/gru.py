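"""Multi-layer bidirectional GRU with explicit backpropagation through time.

Gate layout follows the common (reset, update, candidate) convention:

    r_t = sigmoid(W_ir x_t + b_ir + W_hr h_{t-1} + b_hr)
    z_t = sigmoid(W_iz x_t + b_iz + W_hz h_{t-1} + b_hz)
    n_t = tanh(W_in x_t + b_in + r_t * (W_hn h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

The bidirectional output at step t concatenates the forward state after
consuming frames 0..t with the backward state after consuming frames
T-1..t, so the "final" backward state sits at t = 0 of the output.
"""

from __future__ import annotations

import numpy as np

from .functional import sigmoid
from .layers import Module, Parameter

__all__ = ["GRUDirection", "BiGRU"]


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class GRUDirection(Module):
    """One GRU layer scanned in a single temporal direction."""

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        reverse: bool,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.reverse = reverse
        k = 1.0 / np.sqrt(hidden_size)
        self.w_ih = Parameter(_uniform(rng, (3 * hidden_size, input_size), k))
        self.w_hh = Parameter(_uniform(rng, (3 * hidden_size, hidden_size), k))
        self.b_ih = Parameter(_uniform(rng, (3 * hidden_size,), k))
        self.b_hh = Parameter(_uniform(rng, (3 * hidden_size,), k))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, I) -> hidden states (B, T, H) in original time order."""
        b, t, _ = x.shape
        hs = self.hidden_size
        order = range(t - 1, -1, -1) if self.reverse else range(t)
        # gate pre-activations from the input can be batched over time
        gi_all = x @ self.w_ih.value.T + self.b_ih.value  # (B, T, 3H)
        h = np.zeros((b, hs), dtype=x.dtype)
        out = np.empty((b, t, hs), dtype=x.dtype)
        cache = []
        for step in order:
            gi = gi_all[:, step]
            gh = h @ self.w_hh.value.T + self.b_hh.value
            r = sigmoid(gi[:, :hs] + gh[:, :hs])
            z = sigmoid(gi[:, hs : 2 * hs] + gh[:, hs : 2 * hs])
            ghn = gh[:, 2 * hs :]
            n = np.tanh(gi[:, 2 * hs :] + r * ghn)
            h_new = (1.0 - z) * n + z * h
            cache.append((step, h, r, z, n, ghn))
            out[:, step] = h_new
            h = h_new
        self._cache = (x, cache)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """dout: (B, T, H) gradients on every output state -> dx (B, T, I)."""
        x, cache = self._cache
        hs = self.hidden_size
        dx = np.zeros_like(x)
        dgi_all = np.zeros((x.shape[0], x.shape[1], 3 * hs), dtype=x.dtype)
        dh = np.zeros((x.shape[0], hs), dtype=x.dtype)
        for step, h_prev, r, z, n, ghn in reversed(cache):
            dh = dh + dout[:, step]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dgn = dn * (1.0 - n * n)
            dr = dgn * ghn
            dghn = dgn * r
            dgz = dz * z * (1.0 - z)
            dgr = dr * r * (1.0 - r)
            dgi = np.concatenate([dgr, dgz, dgn], axis=1)
            dgh = np.concatenate([dgr, dgz, dghn], axis=1)
            dgi_all[:, step] = dgi
            self.w_hh.grad += dgh.T @ h_prev
            self.b_hh.grad += dgh.sum(axis=0)
            dh = dh_prev + dgh @ self.w_hh.value
        b, t, _ = x.shape
        flat_x = x.reshape(b * t, -1)
        flat_dgi = dgi_all.reshape(b * t, -1)
        self.w_ih.grad += flat_dgi.T @ flat_x
        self.b_ih.grad += flat_dgi.sum(axis=0)
        dx = dgi_all @ self.w_ih.value
        self._cache = None
        return dx


class BiGRU(Module):
    """Stack of bidirectional GRU layers; output feature size is 2*hidden."""

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        num_layers: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.hidden_size = hidden_size
        self.directions: list[GRUDirection] = []
        in_size = input_size
        for _ in range(num_layers):
            self.directions.append(GRUDirection(in_size, hidden_size, False, rng))
            self.directions.append(GRUDirection(in_size, hidden_size, True, rng))
            in_size = 2 * hidden_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for i in range(0, len(self.directions), 2):
            fwd = self.directions[i](out)
            bwd = self.directions[i + 1](out)
            out = np.concatenate([fwd, bwd], axis=2)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        hs = self.hidden_size
        for i in range(len(self.directions) - 2, -1, -2):
            dfwd = self.directions[i].backward(dout[:, :, :hs])
            dbwd = self.directions[i + 1].backward(dout[:, :, hs:])
            dout = dfwd + dbwd
        return dout

    def final_hidden(self, out: np.ndarray) -> np.ndarray:
        """Concatenate both directions' final states from the top-layer output."""
        hs = self.hidden_size
        return np.concatenate([out[:, -1, :hs], out[:, 0, hs:]], axis=1)

    def inject_final_hidden_grad(
        self, out_shape: tuple[int, int, int], dfinal: np.ndarray
    ) -> np.ndarray:
        """Scatter a gradient on the fused final-state vector back onto the
        per-step output tensor (zeros elsewhere)."""
        hs = self.hidden_size
        dout = np.zeros(out_shape, dtype=dfinal.dtype)
        dout[:, -1, :hs] = dfinal[:, :hs]
        dout[:, 0, hs:] = dfinal[:, hs:]
        return dout
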