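"""Minimal NumPy CNN: 3x3 'same' convolutions, ReLU, 2x2 max pooling, a
global-average-pooling + linear head, softmax cross-entropy and Adam.

Convolutions run as a single float32 GEMM per batch via im2col
(patch matrix (N*H*W, C*9) against the (C*9, F) kernel matrix); the
backward col2im is nine vectorized scatter-adds.  Deterministic for a
fixed seed and thread count.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _im2col(xp: np.ndarray, H: int, W: int) -> np.ndarray:
    """(N, C, H+2, W+2) padded input -> (N*H*W, C*9) patch matrix."""
    N, C = xp.shape[:2]
    # windows: (N, C, H, W, 3, 3) view, no copy
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * 9)
    return np.ascontiguousarray(cols, dtype=DTYPE)


class Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray):
        N, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col(xp, H, Wd)
        out = cols @ self.W + self.b                       # (N*H*W, F)
        out = out.reshape(N, H, Wd, -1).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(out), (cols, (N, C, H, Wd))

    def backward(self, dout: np.ndarray, cache):
        cols, (N, C, H, Wd) = cache
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1).reshape(N * H * Wd, -1), dtype=DTYPE)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W.T                           # (N*H*W, C*9)
        dcols = dcols.reshape(N, H, Wd, C, 3, 3)
        dxp = np.zeros((N, C, H + 2, Wd + 2), dtype=DTYPE)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + H, dj:dj + Wd] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def grads(self):
        return [self.dW, self.db]

    def weights(self):
        return [self.W, self.b]


def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, out > 0


def relu_backward(dout, mask):
    return dout * mask


def avgpool_rows(x: np.ndarray, factor: int):
    """(N, C, H, W) -> (N, C, H//factor, W) average pooling over rows only;
    used as an input stem to reduce the frequency axis."""
    N, C, H, W = x.shape
    H2 = H // factor
    return x[:, :, :H2 * factor, :].reshape(N, C, H2, factor, W).mean(axis=3)


def maxpool2_forward(x):
    """2x2 max pool; odd trailing rows/cols are cropped."""
    N, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    xc = x[:, :, :H2 * 2, :W2 * 2].reshape(N, C, H2, 2, W2, 2)
    out = xc.max(axis=(3, 5))
    mask = xc == out[:, :, :, None, :, None]
    return np.ascontiguousarray(out), (mask, x.shape)


def maxpool2_backward(dout, cache):
    mask, shape = cache
    N, C, H, W = shape
    H2, W2 = H // 2, W // 2
    # ties (rare on continuous activations) split the gradient evenly
    counts = mask.sum(axis=(3, 5), keepdims=True)
    dx = np.zeros(shape, dtype=DTYPE)
    dxc = (mask / counts) * dout[:, :, :, None, :, None]
    dx[:, :, :H2 * 2, :W2 * 2] = dxc.reshape(N, C, H2 * 2, W2 * 2)
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, weights, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w in weights]
        self.v = [np.zeros_like(w) for w in weights]
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        for i, (w, g) in enumerate(zip(weights, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            w -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(w.dtype)


class VGGSmallNet:
    """Optional row-averaging stem, then conv blocks of (filters, reps) 3x3
    convolutions each followed by 2x2 max pooling, then GAP -> linear ->
    softmax over ``n_classes``."""

    def __init__(self, blocks, n_classes: int, input_shape, seed: int,
                 stem_pool: int = 1):
        rng = np.random.default_rng(seed)
        self.blocks = list(blocks)
        self.stem_pool = int(stem_pool)
        self.convs: list[Conv3x3] = []
        c_in = 1
        H, W = input_shape
        H //= self.stem_pool
        for filters, reps in self.blocks:
            for _ in range(reps):
                self.convs.append(Conv3x3(c_in, filters, rng))
                c_in = filters
            H, W = H // 2, W // 2
        if H < 4 or W < 2:
            raise ValueError("final feature map smaller than 4x2; reduce pooling depth")
        self.feature_shape = (c_in, H, W)
        scale = np.sqrt(2.0 / c_in)
        self.Wh = (rng.standard_normal((n_classes, c_in)) * scale).astype(DTYPE)
        self.bh = np.zeros(n_classes, dtype=DTYPE)

    # --- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N, 1, H, W) -> logits (N, n_classes). Also returns the final
        conv feature maps (post-ReLU, pre-GAP)."""
        h = np.ascontiguousarray(x, dtype=DTYPE)
        if self.stem_pool > 1:
            h = avgpool_rows(h, self.stem_pool)
        caches = []
        ci = 0
        for filters, reps in self.blocks:
            for _ in range(reps):
                h, ccache = self.convs[ci].forward(h)
                h, rmask = relu_forward(h)
                caches.append(("conv", ci, ccache, rmask))
                ci += 1
            h, pcache = maxpool2_forward(h)
            caches.append(("pool", None, pcache, None))
        fmap = h                                   # (N, C, Hf, Wf)
        gap = fmap.mean(axis=(2, 3))               # (N, C)
        logits = gap @ self.Wh.T + self.bh
        if want_cache:
            return logits, fmap, (caches, fmap, gap)
        return logits, fmap

    # --- backward ----------------------------------------------------------
    def backward(self, dlogits: np.ndarray, cache):
        caches, fmap, gap = cache
        dlogits = dlogits.astype(DTYPE)
        self.dWh = dlogits.T @ gap
        self.dbh = dlogits.sum(axis=0)
        dgap = dlogits @ self.Wh                   # (N, C)
        _, C, Hf, Wf = fmap.shape
        dh = np.broadcast_to(dgap[:, :, None, None] / (Hf * Wf),
                             fmap.shape).astype(DTYPE)
        for kind, ci, ccache, rmask in reversed(caches):
            if kind == "pool":
                dh = maxpool2_backward(dh, ccache)
            else:
                dh = relu_backward(dh, rmask)
                dh = self.convs[ci].backward(dh, ccache)
        # gradient w.r.t. the (non-trainable) stem is not needed

    def weights(self):
        out = []
        for c in self.convs:
            out.extend(c.weights())
        out.extend([self.Wh, self.bh])
        return out

    def grads(self):
        out = []
        for c in self.convs:
            out.extend(c.grads())
        out.extend([self.dWh, self.dbh])
        return out
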