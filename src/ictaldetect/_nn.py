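"""Minimal numpy neural-network kernels: Adam, an LSTM layer, and an MLP.

Desk-scale replacements for a deep-learning framework: a single LSTM layer
with a dense head (sequence forecasting) and a dense autoencoder (video
volumes), both trained with Adam on mean-squared error. Backward passes are
hand-derived and verified against finite differences in the test suite.
All randomness flows through an explicit numpy Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "LSTMCore", "MLP", "mse"]


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LSTMCore:
    """Single-layer LSTM + dense head mapping a window to the next values.

    Input: ``X`` of shape (batch, T, d_in). The head reads the final hidden
    state (with inverted dropout during training) and emits ``d_out`` values.
    Gate order in the packed weight matrices is (i, f, g, o); the forget-gate
    bias starts at 1 so early training does not wash out the cell state.
    """

    def __init__(self, d_in: int, hidden: int, d_out: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        self.d_in, self.hidden, self.d_out = d_in, hidden, d_out
        self.dropout = dropout
        s = 1.0 / np.sqrt(hidden)
        self.params = {
            "Wx": rng.uniform(-s, s, size=(d_in, 4 * hidden)),
            "Wh": rng.uniform(-s, s, size=(hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
            "Wy": rng.uniform(-s, s, size=(hidden, d_out)),
            "by": np.zeros(d_out),
        }
        self.params["b"][hidden:2 * hidden] = 1.0  # forget gate bias

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        B, T, _ = X.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x_t = X[:, t, :]
            a = x_t @ Wx + h @ Wh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            h_prev_cache = h
            h = o * np.tanh(c)
            cache.append((x_t, h_prev_cache, c_prev, i, f, g, o, c))
        if train and self.dropout > 0.0:
            assert rng is not None
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(h)
        h_drop = h * mask
        y = h_drop @ self.params["Wy"] + self.params["by"]
        return y, (cache, h_drop, mask)

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(X, train=False)
        return y

    # -- backward -----------------------------------------------------------
    def backward(self, dy: np.ndarray, ctx) -> dict:
        """Gradients of the loss w.r.t. all parameters given dL/dy."""
        cache, h_drop, mask = ctx
        H = self.hidden
        Wh, Wy = self.params["Wh"], self.params["Wy"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wy"] = h_drop.T @ dy
        grads["by"] = dy.sum(axis=0)
        dh = (dy @ Wy.T) * mask
        dc = np.zeros_like(dh)
        for t in range(len(cache) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c = cache[t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f  # becomes dc_prev for the next (earlier) step
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            grads["Wx"] += x_t.T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ Wh.T
        return grads


class MLP:
    """Dense network with tanh hidden activations and a linear output layer.

    ``sizes`` lists layer widths input->...->output. Used as the video
    autoencoder (mirrored encoder/decoder widths).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.params = {}
        for k in range(len(sizes) - 1):
            s = np.sqrt(6.0 / (sizes[k] + sizes[k + 1]))
            self.params[f"W{k}"] = rng.uniform(-s, s, size=(sizes[k], sizes[k + 1]))
            self.params[f"b{k}"] = np.zeros(sizes[k + 1])

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for k in range(self.n_layers):
            z = h @ self.params[f"W{k}"] + self.params[f"b{k}"]
            h = z if k == self.n_layers - 1 else np.tanh(z)
            acts.append(h)
        return h, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(X)
        return y

    def backward(self, dy: np.ndarray, acts) -> dict:
        grads = {}
        delta = dy
        for k in range(self.n_layers - 1, -1, -1):
            grads[f"W{k}"] = acts[k].T @ delta
            grads[f"b{k}"] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.params[f"W{k}"].T) * (1.0 - acts[k] ** 2)
        return grads
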