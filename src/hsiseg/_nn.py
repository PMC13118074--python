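"""Minimal 1-D convolutional network with Adam, in pure numpy.

Architecture (per-pixel spectrum of length B as a 1-channel signal):
three convolutional blocks (kernel length 5, 8 feature maps, same
padding, batch normalization, ReLU), global average pooling over the
spectral axis, dense layers 64 and 16 with ReLU, and a 2-way softmax.
Training is full backpropagation with cross-entropy loss and the Adam
update; all initialization and shuffling comes from one seeded
generator, so runs are bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SpectralConvNet"]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-D convolution. x: (N, C, L); W: (O, C, K)."""
    K = W.shape[2]
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, K, axis=2)          # (N, C, L, K)
    y = np.einsum("nclk,ock->nol", win, W, optimize=True) + b[None, :, None]
    return y, win


def _conv_backward(dy: np.ndarray, win: np.ndarray, W: np.ndarray):
    K = W.shape[2]
    pad = K // 2
    dW = np.einsum("nclk,nol->ock", win, dy, optimize=True)
    db = dy.sum(axis=(0, 2))
    dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad)))
    dwin = sliding_window_view(dyp, K, axis=2)        # (N, O, L, K)
    dx = np.einsum("nolk,ock->ncl", dwin, W[:, :, ::-1], optimize=True)
    return dx, dW, db


class _BatchNorm:
    """Per-channel batch normalization over (N, L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray):
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        dx = (inv[None, :, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )
        return dx, dgamma, dbeta


class SpectralConvNet:
    """The 3-block spectral CNN with its Adam state."""

    KERNEL = 5
    CHANNELS = 8
    HIDDEN = (64, 16)
    N_CLASSES = 2

    def __init__(self, n_bands: int, seed: int = 0):
        if n_bands < self.KERNEL:
            raise ValueError(
                f"spectra must have at least {self.KERNEL} bands")
        self.n_bands = n_bands
        rng = np.random.default_rng(seed)
        C, K = self.CHANNELS, self.KERNEL

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params: dict[str, np.ndarray] = {
            "W1": he((C, 1, K), K), "b1": np.zeros(C),
            "W2": he((C, C, K), C * K), "b2": np.zeros(C),
            "W3": he((C, C, K), C * K), "b3": np.zeros(C),
            "Wf1": he((C, self.HIDDEN[0]), C), "bf1": np.zeros(self.HIDDEN[0]),
            "Wf2": he((self.HIDDEN[0], self.HIDDEN[1]), self.HIDDEN[0]),
            "bf2": np.zeros(self.HIDDEN[1]),
            "Wf3": he((self.HIDDEN[1], self.N_CLASSES), self.HIDDEN[1]),
            "bf3": np.zeros(self.N_CLASSES),
        }
        self.bns = [_BatchNorm(C) for _ in range(3)]
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        for i, bn in enumerate(self.bns):
            for name in ("gamma", "beta"):
                key = f"bn{i}_{name}"
                self._adam_m[key] = np.zeros_like(getattr(bn, name))
                self._adam_v[key] = np.zeros_like(getattr(bn, name))
        self._adam_t = 0

    # ------------------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        n = sum(v.size for v in self.params.values())
        n += sum(bn.gamma.size + bn.beta.size for bn in self.bns)
        return n

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False):
        """x: (N, B) spectra. Returns class probabilities (N, 2)."""
        cache: dict[str, object] = {}
        a = x[:, None, :]                                  # (N, 1, B)
        for blk in (1, 2, 3):
            z, win = _conv_forward(a, self.params[f"W{blk}"],
                                   self.params[f"b{blk}"])
            zb = self.bns[blk - 1].forward(z, training)
            a_new = np.maximum(zb, 0.0)
            cache[f"win{blk}"] = win
            cache[f"relu{blk}"] = zb > 0
            a = a_new
        g = a.mean(axis=2)                                 # GAP -> (N, 8)
        cache["gap_len"] = a.shape[2]
        h1 = g @ self.params["Wf1"] + self.params["bf1"]
        r1 = np.maximum(h1, 0.0)
        h2 = r1 @ self.params["Wf2"] + self.params["bf2"]
        r2 = np.maximum(h2, 0.0)
        logits = r2 @ self.params["Wf3"] + self.params["bf3"]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache.update(g=g, h1=h1, r1=r1, h2=h2, r2=r2, probs=probs)
        self._cache = cache
        return probs

    # ------------------------------------------------------------------
    def _backward(self, y: np.ndarray):
        """Cross-entropy gradient for integer labels y in {0, 1}."""
        c = self._cache
        N = y.size
        grads: dict[str, np.ndarray] = {}
        dlogits = c["probs"].copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N
        grads["Wf3"] = c["r2"].T @ dlogits
        grads["bf3"] = dlogits.sum(axis=0)
        dr2 = dlogits @ self.params["Wf3"].T
        dh2 = dr2 * (c["h2"] > 0)
        grads["Wf2"] = c["r1"].T @ dh2
        grads["bf2"] = dh2.sum(axis=0)
        dr1 = dh2 @ self.params["Wf2"].T
        dh1 = dr1 * (c["h1"] > 0)
        grads["Wf1"] = c["g"].T @ dh1
        grads["bf1"] = dh1.sum(axis=0)
        dg = dh1 @ self.params["Wf1"].T                    # (N, 8)
        L = c["gap_len"]
        da = np.repeat(dg[:, :, None] / L, L, axis=2)
        for blk in (3, 2, 1):
            dzb = da * c[f"relu{blk}"]
            dz, dgamma, dbeta = self.bns[blk - 1].backward(dzb)
            grads[f"bn{blk - 1}_gamma"] = dgamma
            grads[f"bn{blk - 1}_beta"] = dbeta
            da, dW, db = _conv_backward(dz, c[f"win{blk}"],
                                        self.params[f"W{blk}"])
            grads[f"W{blk}"] = dW
            grads[f"b{blk}"] = db
        return grads

    # ------------------------------------------------------------------
    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t

        def update(key, param, grad):
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * grad
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * grad**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            param -= lr * mhat / (np.sqrt(vhat) + eps)

        for key, grad in grads.items():
            if key.startswith("bn"):
                idx, name = int(key[2]), key.split("_")[1]
                update(key, getattr(self.bns[idx], name), grad)
            else:
                update(key, self.params[key], grad)

    # ------------------------------------------------------------------
    def train(self, X: np.ndarray, y: np.ndarray, epochs: int,
              batch_size: int, lr: float, seed: int) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss."""
        rng = np.random.default_rng(seed)
        N = X.shape[0]
        bs = min(batch_size, N)
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(N)
            losses = []
            for start in range(0, N, bs):
                idx = order[start:start + bs]
                probs = self.forward(X[idx], training=True)
                loss = -np.mean(np.log(probs[np.arange(idx.size), y[idx]] + 1e-12))
                grads = self._backward(y[idx])
                self._adam_step(grads, lr)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)
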