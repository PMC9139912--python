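"""Minimal deterministic CNN in numpy: layers, loss, Adam.

This backs the desk-scale ``tinycnn`` architecture: three 3x3
convolution + ReLU + 2x2 average-pool blocks, a flatten, and a dense head
(linear -> ReLU -> dropout -> linear to 2 logits) trained with softmax
cross-entropy and Adam. Everything runs single-threaded on float32 and is
bit-deterministic given the seed, which is what the reproducibility
contract of the experiment harness requires.

Shapes follow the (N, C, H, W) convention. Convolutions use stride 1 and
'same' zero padding; average pooling floors odd extents (the trailing
row/column is dropped), so any input size >= 8 works.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["TinyCNNNet", "softmax", "cross_entropy_grad"]

_K = 3  # conv kernel size
_PAD = 1


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = len(y)
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patch matrix for a same-padded 3x3 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (_PAD, _PAD), (_PAD, _PAD)))
    patches = [xp[:, :, i : i + h, j : j + w] for i in range(_K) for j in range(_K)]
    # (N, C, 9, H, W) -> (N, C*9, H*W)
    return np.stack(patches, axis=2).reshape(n, c * _K * _K, h * w)


def _col2im(dcols: np.ndarray, x_shape) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * _PAD, w + 2 * _PAD), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, _K * _K, h, w)
    for idx in range(_K * _K):
        i, j = divmod(idx, _K)
        dxp[:, :, i : i + h, j : j + w] += dcols[:, :, idx]
    return dxp[:, :, _PAD : _PAD + h, _PAD : _PAD + w]


class _Conv:
    def __init__(self, rng, in_ch, out_ch):
        fan_in = in_ch * _K * _K
        self.w = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x):
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = np.matmul(self.w, cols) + self.b[:, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h, w)

    def backward(self, dout):
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        doutf = dout.reshape(n, -1, h * w)
        self.dw = np.einsum("nos,nks->ok", doutf, cols).astype(np.float32)
        self.db = doutf.sum(axis=(0, 2)).astype(np.float32)
        dcols = np.matmul(self.w.T, doutf)
        return _col2im(dcols, x_shape)

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.dw, self.db])


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.dw, self.db])


def _relu_fwd(x):
    return np.maximum(x, 0.0), x > 0


def _avgpool_fwd(x):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    return xc.mean(axis=(3, 5)), (h, w)


def _avgpool_bwd(dout, hw):
    h, w = hw
    n, c, h2, w2 = dout.shape
    dx = np.zeros((n, c, h, w), dtype=dout.dtype)
    spread = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * 0.25
    dx[:, :, : h2 * 2, : w2 * 2] = spread
    return dx


class TinyCNNNet:
    """3-block CNN with a linear/ReLU/dropout/linear binary head."""

    CHANNELS = (8, 16, 32)
    HIDDEN = 64

    def __init__(self, input_shape: tuple[int, int, int], dropout: float, seed: int):
        c, h, w = input_shape
        if h < 8 or w < 8:
            raise ValueError(f"tinycnn needs at least 8x8 inputs, got {h}x{w}")
        self.input_shape = (c, h, w)
        self.dropout = float(dropout)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        chans = (c,) + self.CHANNELS
        self.convs = [_Conv(rng, chans[i], chans[i + 1]) for i in range(3)]
        for _ in range(3):
            h, w = h // 2, w // 2
        self.flat_dim = self.CHANNELS[-1] * h * w
        self.fc1 = _Dense(rng, self.flat_dim, self.HIDDEN)
        self.fc2 = _Dense(rng, self.HIDDEN, 2)
        self._drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._caches = []
        for conv in self.convs:
            x = conv.forward(x)
            x, mask = _relu_fwd(x)
            x, hw = _avgpool_fwd(x)
            self._caches.append((mask, hw))
        n = len(x)
        x = x.reshape(n, self.flat_dim)
        x = self.fc1.forward(x)
        x, self._head_mask = _relu_fwd(x)
        if train and self.dropout > 0:
            keep = (self._drop_rng.random(x.shape) >= self.dropout).astype(np.float32)
            self._drop_mask = keep / (1.0 - self.dropout)
            x = x * self._drop_mask
        else:
            self._drop_mask = None
        return self.fc2.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits)
        if self._drop_mask is not None:
            d = d * self._drop_mask
        d = d * self._head_mask
        d = self.fc1.backward(d)
        d = d.reshape(len(d), self.CHANNELS[-1], *self._pooled_hw())
        for conv, (mask, hw) in zip(reversed(self.convs), reversed(self._caches)):
            d = _avgpool_bwd(d, hw)
            d = d * mask
            d = conv.backward(d)

    def _pooled_hw(self):
        _, h, w = self.input_shape
        for _ in range(3):
            h, w = h // 2, w // 2
        return h, w

    # -- parameters --------------------------------------------------------
    @property
    def layers(self):
        return self.convs + [self.fc1, self.fc2]

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p, dtype=np.float32).tobytes())
        return h.hexdigest()

    def state(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p for i, p in enumerate(self.parameters())}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p[...] = state[f"param_{i}"]


class Adam:
    """Adaptive moment estimation with the standard defaults."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
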