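"""A compact numpy engine for the Inception-style 1-D convolutional regressor.

Implements exactly the layers the gestational-age clock needs — same-padded
1-D convolutions, channelwise layer normalization, ReLU, stride-1 max
pooling, global average pooling and dense layers — with hand-written
backpropagation (through to the input, which integrated-gradients
attribution consumes) and an Adam optimizer with L2 weight decay and
reduce-on-plateau learning-rate scheduling.

Activations are laid out channels-first as (C, B, L) so convolutions reduce
to a handful of BLAS matmuls per kernel tap; float32 is the default compute
dtype (float64 available for gradient checking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv1d:
    """Same-padded cross-correlation along the last axis; odd kernel only."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, dtype=np.float32):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self._xp = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c_in, B, L = x.shape
        K, P = self.kernel, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (P, P)))
        self._xp = xp
        self._shape = (B, L)
        out = np.zeros((self.W.value.shape[0], B * L), dtype=x.dtype)
        for k in range(K):
            sl = np.ascontiguousarray(xp[:, :, k : k + L]).reshape(c_in, B * L)
            out += self.W.value[:, :, k] @ sl
        out += self.b.value[:, None]
        return out.reshape(-1, B, L)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c_out, B, L = dout.shape
        K, P = self.kernel, self.pad
        xp = self._xp
        c_in = xp.shape[0]
        dmat = dout.reshape(c_out, B * L)
        self.b.grad += dmat.sum(axis=1)
        dxp = np.zeros_like(xp)
        for k in range(K):
            sl = np.ascontiguousarray(xp[:, :, k : k + L]).reshape(c_in, B * L)
            self.W.grad[:, :, k] += dmat @ sl.T
            dxp[:, :, k : k + L] += (self.W.value[:, :, k].T @ dmat).reshape(c_in, B, L)
        self._xp = None
        return dxp[:, :, P : P + L] if P else dxp


class LayerNorm:
    """Normalize across channels per (sample, time) position."""

    def __init__(self, c: int, dtype=np.float32, eps: float = 1e-5):
        self.g = Param(np.ones((c, 1, 1), dtype=dtype))
        self.beta = Param(np.zeros((c, 1, 1), dtype=dtype))
        self.eps = eps

    @property
    def params(self):
        return [self.g, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0, keepdims=True)
        var = x.var(axis=0, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.g.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.g.grad += (dout * xhat).sum(axis=(1, 2), keepdims=True)
        self.beta.grad += dout.sum(axis=(1, 2), keepdims=True)
        dxhat = dout * self.g.value
        dx = inv * (
            dxhat
            - dxhat.mean(axis=0, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=0, keepdims=True)
        )
        self._xhat = self._inv = None
        return dx


class ReLU:
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class MaxPoolSame:
    """Stride-1 max pooling with same padding (window 3 by default)."""

    params: list = []

    def __init__(self, window: int = 3):
        if window % 2 == 0:
            raise ValueError("window must be odd")
        self.window = window

    def forward(self, x):
        P = (self.window - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (P, P)), constant_values=-np.inf)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.window, axis=2)
        self._idx = windows.argmax(axis=3)
        self._shape = x.shape
        return windows.max(axis=3)

    def backward(self, dout):
        C, B, L = self._shape
        dx = np.zeros((C, B, L + self.window - 1), dtype=dout.dtype)
        P = (self.window - 1) // 2
        for k in range(self.window):
            mask = self._idx == k
            dx[:, :, k : k + L] += dout * mask
        self._idx = None
        return dx[:, :, P : P + L]


class Linear:
    def __init__(self, c_in: int, c_out: int, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):  # x: (Cin, B)
        self._x = x
        return self.W.value @ x + self.b.value[:, None]

    def backward(self, dout):
        self.W.grad += dout @ self._x.T
        self.b.grad += dout.sum(axis=1)
        dx = self.W.value.T @ dout
        self._x = None
        return dx


class InceptionBlock:
    """Bottleneck 1x1 conv -> parallel convolutions + max-pool branch ->
    concatenate -> layer normalization (ReLU applied by the network, after
    any residual addition)."""

    def __init__(self, c_in, bottleneck, width, kernel_sizes, rng, dtype=np.float32):
        self.bottleneck = Conv1d(c_in, bottleneck, 1, rng, dtype)
        self.branches = [Conv1d(bottleneck, width, k, rng, dtype) for k in kernel_sizes]
        self.pool = MaxPoolSame(3)
        self.pool_conv = Conv1d(c_in, width, 1, rng, dtype)
        self.c_out = width * (len(kernel_sizes) + 1)
        self.norm = LayerNorm(self.c_out, dtype)

    @property
    def params(self):
        out = list(self.bottleneck.params) + list(self.pool_conv.params) + list(self.norm.params)
        for br in self.branches:
            out += br.params
        return out

    def forward(self, x):
        z = self.bottleneck.forward(x)
        parts = [br.forward(z) for br in self.branches]
        parts.append(self.pool_conv.forward(self.pool.forward(x)))
        self._widths = [p.shape[0] for p in parts]
        return self.norm.forward(np.concatenate(parts, axis=0))

    def backward(self, dout):
        dcat = self.norm.backward(dout)
        offsets = np.cumsum([0] + self._widths)
        dz = None
        for br, lo, hi in zip(self.branches, offsets[:-1], offsets[1:]):
            part = br.backward(dcat[lo:hi])
            dz = part if dz is None else dz + part
        dpool = self.pool.backward(self.pool_conv.backward(dcat[offsets[-2] : offsets[-1]]))
        return self.bottleneck.backward(dz) + dpool


class InceptionRegressor:
    """Stack of Inception blocks with a residual connection every third block,
    global average pooling into the embedding, and a nonlinear scalar head."""

    def __init__(
        self,
        in_channels: int = 2,
        n_blocks: int = 9,
        bottleneck: int = 32,
        embed_dim: int = 128,
        kernel_sizes: Sequence[int] = (9, 19, 39),
        seed: int = 0,
        dtype=np.float32,
        residual_every: int = 3,
    ):
        n_branches = len(kernel_sizes) + 1
        if embed_dim % n_branches:
            raise ValueError(f"embed_dim must be divisible by {n_branches}")
        width = embed_dim // n_branches
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.residual_every = residual_every
        self.blocks, self.relus = [], []
        self.shortcuts = {}
        c = in_channels
        residual_c = in_channels
        for i in range(n_blocks):
            block = InceptionBlock(c, bottleneck, width, kernel_sizes, rng, dtype)
            self.blocks.append(block)
            self.relus.append(ReLU())
            if residual_every and (i + 1) % residual_every == 0:
                self.shortcuts[i] = (
                    Conv1d(residual_c, block.c_out, 1, rng, dtype),
                    LayerNorm(block.c_out, dtype),
                )
                residual_c = block.c_out
            c = block.c_out
        self.embed_dim = c
        self.fc1 = Linear(c, max(c // 2, 8), rng, dtype)
        self.head_relu = ReLU()
        self.fc2 = Linear(max(c // 2, 8), 1, rng, dtype)

    @property
    def params(self):
        out = []
        for b in self.blocks:
            out += b.params
        for conv, norm in self.shortcuts.values():
            out += conv.params + norm.params
        out += self.fc1.params + self.fc2.params
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    # -- forward / backward -------------------------------------------------
    def forward(self, x_batch: np.ndarray, want_embedding: bool = False):
        """x_batch: (B, C, L) -> predictions (B,) [, embeddings (B, embed_dim)]."""
        x = np.ascontiguousarray(np.transpose(np.asarray(x_batch, self.dtype), (1, 0, 2)))
        res_input = x
        for i, (block, relu) in enumerate(zip(self.blocks, self.relus)):
            z = block.forward(x)
            if i in self.shortcuts:
                conv, norm = self.shortcuts[i]
                z = z + norm.forward(conv.forward(res_input))
                x = relu.forward(z)
                res_input = x
            else:
                x = relu.forward(z)
        self._L = x.shape[2]
        emb = x.mean(axis=2)  # (C, B) global average pooling
        h = self.head_relu.forward(self.fc1.forward(emb))
        pred = self.fc2.forward(h)[0]
        if want_embedding:
            return pred, emb.T.copy()
        return pred

    def backward(self, dpred: np.ndarray) -> np.ndarray:
        """dpred: (B,) -> gradient w.r.t. the input batch (B, C, L)."""
        dh = self.fc2.backward(dpred[None, :].astype(self.dtype))
        demb = self.fc1.backward(self.head_relu.backward(dh))
        dx = np.repeat(demb[:, :, None] / self._L, self._L, axis=2)
        # `pending` carries the gradient owed to the activation that fed a
        # later shortcut: that activation is the output of the previous
        # shortcut block (or the network input for the first one).
        pending = None
        for i in range(len(self.blocks) - 1, -1, -1):
            if i in self.shortcuts and pending is not None:
                dx = dx + pending
                pending = None
            dz = self.relus[i].backward(dx)
            if i in self.shortcuts:
                conv, norm = self.shortcuts[i]
                pending = conv.backward(norm.backward(dz))
            dx = self.blocks[i].backward(dz)
        if pending is not None:
            dx = dx + pending
        return np.transpose(dx, (1, 0, 2))

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    # -- (de)serialization --------------------------------------------------
    def state(self) -> list:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor=0.5, patience=10, min_lr=1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
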