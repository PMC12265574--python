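"""Compact multi-resolution convolutional heatmap network.

A small image-to-heatmap model in the spirit of high-resolution keypoint
networks: a high-resolution branch is kept alongside a coarser branch and
the two are fused before the head, giving the large receptive field the
broad holographic fringes require while preserving localization.  The
network maps a normalized hologram to per-pixel cell-presence logits at
1/4 resolution (stride 4); a sigmoid turns logits into probabilities.

Implemented directly on numpy (im2col convolutions with hand-written
backward passes and an Adam optimizer) — at the desk scale used here
(~11k parameters) this trains on one CPU in minutes and is exactly
reproducible for a fixed seed.
"""

from __future__ import annotations

import io
import math

import numpy as np

__all__ = ["Conv2D", "HeatmapNet", "Adam", "sigmoid", "save_model", "load_model"]

STRIDE = 4          # heatmap stride relative to input pixels
_ALIGN = 8          # input padded to a multiple of this before forward


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2D:
    """Same-padded 2-D convolution with stride, optional ReLU."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 relu: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.k, self.stride, self.relu = k, stride, relu
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (N, C, H, W); H, W divisible by stride
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (N, C, Ho, Wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
        out = cols @ self.w.reshape(len(self.w), -1).T + self.b
        out = out.transpose(0, 3, 1, 2)                 # (N, cout, Ho, Wo)
        if self.relu:
            mask = out > 0
            out = out * mask
        else:
            mask = None
        if train:
            self._cache = (cols, x.shape, mask)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape, mask = self._cache
        if mask is not None:
            grad = grad * mask
        n, c, h, w = xshape
        k, s = self.k, self.stride
        p = k // 2
        g = grad.transpose(0, 2, 3, 1)                  # (N, Ho, Wo, cout)
        ho, wo = g.shape[1], g.shape[2]
        self.dw = (g.reshape(-1, g.shape[-1]).T @ cols.reshape(-1, cols.shape[-1])
                   ).reshape(self.w.shape)
        self.db = g.sum(axis=(0, 1, 2))
        # gradient w.r.t. input: scatter col-gradients back (col2im)
        gcols = g @ self.w.reshape(len(self.w), -1)      # (N, Ho, Wo, C*k*k)
        gcols = gcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _downgrad2(g: np.ndarray) -> np.ndarray:
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class HeatmapNet:
    """Two-branch heatmap detector, output stride 4, sigmoid head."""

    def __init__(self, seed: int = 0, width: int = 16):
        rng = np.random.default_rng(seed)
        w = width
        self.c1 = Conv2D(1, w // 2, 5, stride=2, rng=rng)
        self.c2 = Conv2D(w // 2, w, 3, stride=2, rng=rng)
        self.d1 = Conv2D(w, w, 3, stride=2, rng=rng)     # coarse branch, stride 8
        self.d2 = Conv2D(w, w, 3, stride=1, rng=rng)
        self.f1 = Conv2D(w, w, 3, stride=1, rng=rng)     # fusion at stride 4
        self.head = Conv2D(w, 1, 1, stride=1, relu=False, rng=rng)
        self.head.b[:] = -4.0   # start near-zero probability everywhere
        self.layers = [self.c1, self.c2, self.d1, self.d2, self.f1, self.head]
        self.stride = STRIDE

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) with H, W multiples of 8 -> logits (N, 1, H/4, W/4)."""
        h1 = self.c2.forward(self.c1.forward(x, train), train)   # stride 4
        lo = self.d2.forward(self.d1.forward(h1, train), train)  # stride 8
        fused = h1 + _upsample2(lo)
        z = self.head.forward(self.f1.forward(fused, train), train)
        return z

    def backward(self, dz: np.ndarray) -> None:
        dfused = self.f1.backward(self.head.backward(dz))
        dlo = _downgrad2(dfused)
        dh1 = dfused + self.d1.backward(self.d2.backward(dlo))
        self.c1.backward(self.c2.backward(dh1))

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Heatmap probabilities for one 2-D normalized image.

        Pads to the internal alignment, runs the network in evaluation
        mode, crops to ``ceil(shape / stride)`` and bounds to [0, 1].
        """
        img = np.asarray(image, dtype=float)
        h, w = img.shape
        ph = (-h) % _ALIGN
        pw = (-w) % _ALIGN
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        z = self.forward_logits(img[None, None], train=False)[0, 0]
        hm = sigmoid(z)
        return hm[: -(-h // STRIDE), : -(-w // STRIDE)]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class Adam:
    """Adam optimizer over a parameter list (updated in place)."""

    def __init__(self, params, lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, clip: float | None = 5.0) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if clip is not None:
                norm = np.linalg.norm(g)
                if norm > clip:
                    g = g * (clip / norm)
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_model(model: HeatmapNet, path, extra: dict | None = None) -> None:
    """Serialize weights (and optional metadata) to an .npz file."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        arrays[f"w{i}"] = layer.w
        arrays[f"b{i}"] = layer.b
    if extra:
        for k, val in extra.items():
            arrays[f"meta_{k}"] = np.asarray(val)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> HeatmapNet:
    data = np.load(path)
    width = data["b1"].size
    model = HeatmapNet(width=width)
    for i, layer in enumerate(model.layers):
        layer.w = data[f"w{i}"]
        layer.b = data[f"b{i}"]
    return model
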