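"""Minimal convolutional backbones for tile classification.

The default "tiny" backbone is two 3x3 convolution blocks (conv -> ReLU ->
max-pool), a flattened feature vector with dropout, and a linear head over
two (or K) logits, trained with Adam on the softmax cross-entropy. It is
implemented directly on numpy (im2col convolutions, exact backprop —
gradient-checked in the test suite) so the full pipeline runs on one CPU.
Deeper architectures can be registered under the same contract.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyConvNet", "BACKBONES", "make_backbone", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _he_init(shape, fan_in, rng):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class TinyConvNet:
    """Two conv blocks + pooling + dropout + linear head.

    Weights for a conv layer are stored as (C_in, k, k, F); forward uses
    im2col (sliding windows flattened to columns) so convolution is one
    matrix product.
    """

    def __init__(self, input_shape=(64, 64, 3), n_classes: int = 2,
                 n_filters=(8, 16), kernel: int = 3, dropout: float = 0.33,
                 seed: int = 0):
        h, w, c = input_shape
        self.input_shape = tuple(input_shape)
        self.n_classes = int(n_classes)
        self.kernel = int(kernel)
        self.dropout = float(dropout)
        f1, f2 = n_filters
        k = self.kernel
        # Pool sizes adapt to the input so the final map stays >= 2x2.
        self.pool1 = 4 if min(h, w) >= 48 else 2
        h1, w1 = (h - k + 1) // self.pool1, (w - k + 1) // self.pool1
        self.pool2 = 4 if min(h1, w1) >= 14 else 2
        h2, w2 = (h1 - k + 1) // self.pool2, (w1 - k + 1) // self.pool2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"input {input_shape} too small for this net")
        self.feat_dim = h2 * w2 * f2

        rng = np.random.default_rng(seed)
        self.params = {
            "W1": _he_init((c, k, k, f1), c * k * k, rng),
            "b1": np.zeros(f1, dtype=np.float32),
            "W2": _he_init((f1, k, k, f2), f1 * k * k, rng),
            "b2": np.zeros(f2, dtype=np.float32),
            "Wf": _he_init((self.feat_dim, self.n_classes), self.feat_dim, rng),
            "bf": np.zeros(self.n_classes, dtype=np.float32),
        }

    # -- layers ------------------------------------------------------------
    @staticmethod
    def _conv_forward(x, W, b):
        # x: (N, H, W, C); W: (C, k, k, F)
        k = W.shape[1]
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,OH,OW,C,k,k)
        n, oh, ow = win.shape[:3]
        cols = win.reshape(n, oh, ow, -1)                  # C*k*k, C-major
        Wm = W.reshape(-1, W.shape[-1])
        out = cols @ Wm + b
        return out, (cols, x.shape, W.shape)

    @staticmethod
    def _conv_backward(dout, cache, W):
        cols, x_shape, w_shape = cache
        c, k, _, f = w_shape
        n, oh, ow, _ = dout.shape
        dW = (cols.reshape(-1, c * k * k).T
              @ dout.reshape(-1, f)).reshape(w_shape)
        db = dout.sum(axis=(0, 1, 2))
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                # (N,OH,OW,F) x (C,F) -> (N,OH,OW,C)
                dx[:, i:i + oh, j:j + ow, :] += np.tensordot(
                    dout, W[:, i, j, :], axes=([3], [1]))
        return dx, dW, db

    @staticmethod
    def _pool_forward(x, p):
        n, h, w, c = x.shape
        oh, ow = h // p, w // p
        x6 = x[:, :oh * p, :ow * p, :].reshape(n, oh, p, ow, p, c)
        out = x6.max(axis=(2, 4))
        return out, (x6, x.shape, p)

    @staticmethod
    def _pool_backward(dout, cache):
        x6, x_shape, p = cache
        n, oh, _, ow, _, c = x6.shape
        m = x6.max(axis=(2, 4), keepdims=True)
        mask = (x6 == m)
        cnt = mask.sum(axis=(2, 4), keepdims=True)
        d6 = mask * (dout[:, :, None, :, None, :] / cnt)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, :oh * p, :ow * p, :] = d6.reshape(n, oh * p, ow * p, c)
        return dx

    # -- full network ------------------------------------------------------
    def forward(self, x, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return logits and the cache needed for backprop. Dropout is
        active only when ``train`` is true."""
        p = self.params
        z1, c1 = self._conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0)
        p1, cp1 = self._pool_forward(a1, self.pool1)
        z2, c2 = self._conv_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0)
        p2, cp2 = self._pool_forward(a2, self.pool2)
        h = p2.reshape(x.shape[0], -1)
        if train and self.dropout > 0:
            if rng is None:
                rng = np.random.default_rng()
            keep = 1.0 - self.dropout
            dmask = (rng.random(h.shape) < keep).astype(np.float32) / keep
            hd = h * dmask
        else:
            dmask = None
            hd = h
        logits = hd @ p["Wf"] + p["bf"]
        cache = (c1, z1, cp1, c2, z2, cp2, p2.shape, hd, dmask)
        return logits, cache

    def loss_and_grads(self, x, y, train: bool = True,
                       rng: np.random.Generator | None = None):
        """Mean softmax cross-entropy and gradients for all parameters.
        ``y`` holds integer class indices."""
        p = self.params
        logits, cache = self.forward(x, train=train, rng=rng)
        c1, z1, cp1, c2, z2, cp2, p2shape, hd, dmask = cache
        n = x.shape[0]
        probs = softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads = {}
        grads["Wf"] = hd.T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wf"].T
        if dmask is not None:
            dh = dh * dmask
        dp2 = dh.reshape(p2shape)
        da2 = self._pool_backward(dp2, cp2)
        dz2 = da2 * (z2 > 0)
        dp1, grads["W2"], grads["b2"] = self._conv_backward(dz2, c2, p["W2"])
        da1 = self._pool_backward(dp1, cp1)
        dz1 = da1 * (z1 > 0)
        _, grads["W1"], grads["b1"] = self._conv_backward(dz1, c1, p["W1"])
        return loss, grads

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self.forward(x, train=False)
        return softmax(logits)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(weights[k], dtype=np.float32).copy()


class Adam:
    """Adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k].astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


BACKBONES = {
    "tiny": TinyConvNet,
}


def make_backbone(name: str, input_shape, n_classes: int, dropout: float,
                  seed: int):
    if name not in BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; "
                       f"registered: {sorted(BACKBONES)}")
    return BACKBONES[name](input_shape=input_shape, n_classes=n_classes,
                           dropout=dropout, seed=seed)
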