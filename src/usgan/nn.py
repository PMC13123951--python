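"""Minimal numpy neural-network layers with explicit forward/backward passes.

Every layer follows the same functional contract:

    y, cache = layer.forward(x)
    dx = layer.backward(dy, cache)

``backward`` accumulates parameter gradients into ``layer.g`` (so a layer
applied several times inside one optimization step — the shared generator is
run up to six times per training step — sums its gradients), and returns the
gradient with respect to the input. ``zero_grad`` resets the accumulators.

Convolutions are computed by im2col + matrix multiplication; all randomness
in initialization flows from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# im2col / col2im


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:pad + h, pad:pad + w]
    return dxp


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base class holding parameter (`p`) and gradient (`g`) dictionaries."""

    def __init__(self):
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.p:
            self.g[k] = np.zeros_like(self.p[k])


class Conv2d(Layer):
    """2-D convolution (cross-correlation), zero padding, square kernel."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 init_std: float = 0.02, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        self.p["W"] = (rng.standard_normal((cout, cin, k, k)) * init_std).astype(dtype)
        self.p["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray):
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.p["W"].reshape(self.cout, -1)
        out = np.einsum("of,nfp->nop", wmat, cols, optimize=True)
        out += self.p["b"][None, :, None]
        n = x.shape[0]
        return out.reshape(n, self.cout, ho, wo), (x.shape, cols, ho, wo)

    def backward(self, dy: np.ndarray, cache, accumulate: bool = True):
        xshape, cols, ho, wo = cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, ho * wo)
        if accumulate:
            dW = np.einsum("nop,nfp->of", dyf, cols, optimize=True)
            self.g["W"] += dW.reshape(self.p["W"].shape).astype(self.p["W"].dtype)
            self.g["b"] += dyf.sum(axis=(0, 2)).astype(self.p["b"].dtype)
        wmat = self.p["W"].reshape(self.cout, -1)
        dcols = np.einsum("of,nop->nfp", wmat, dyf, optimize=True)
        return _col2im(dcols, xshape, self.k, self.k, self.stride, self.pad, ho, wo)


def _channel_stats(x: np.ndarray, eps: float):
    """Per-(sample, channel) spatial mean and (population std + eps)."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    u = x - mu
    sigma = np.sqrt((u * u).mean(axis=(2, 3), keepdims=True))
    return mu, u, sigma + eps


def _norm_backward(dxhat: np.ndarray, u: np.ndarray, s: np.ndarray, eps: float,
                   sigma_floor: float = 1e-12) -> np.ndarray:
    """Backprop through xhat = u / s, u = x - mean(x), s = sqrt(mean u^2) + eps."""
    m = u.shape[2] * u.shape[3]
    sigma = np.maximum(s - eps, sigma_floor)
    proj = (dxhat * u).sum(axis=(2, 3), keepdims=True)
    du = dxhat / s - proj / (s * s) * u / (m * sigma)
    return du - du.mean(axis=(2, 3), keepdims=True)


class InstanceNorm2d(Layer):
    """Per-channel spatial normalization with learnable affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.p["gamma"] = np.ones(channels, dtype=dtype)
        self.p["beta"] = np.zeros(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray):
        mu, u, s = _channel_stats(x, self.eps)
        xhat = u / s
        y = self.p["gamma"][None, :, None, None] * xhat + self.p["beta"][None, :, None, None]
        return y, (u, s, xhat)

    def backward(self, dy: np.ndarray, cache, accumulate: bool = True):
        u, s, xhat = cache
        if accumulate:
            self.g["gamma"] += (dy * xhat).sum(axis=(0, 2, 3)).astype(self.p["gamma"].dtype)
            self.g["beta"] += dy.sum(axis=(0, 2, 3)).astype(self.p["beta"].dtype)
        dxhat = dy * self.p["gamma"][None, :, None, None]
        return _norm_backward(dxhat, u, s, self.eps)


class AdaIN(Layer):
    """Adaptive instance normalization: re-normalize each channel's spatial
    statistics to an externally supplied (shift, scale) pair.

        out_c = scale_c * (x_c - mean(x_c)) / (std(x_c) + eps) + shift_c

    The layer owns no parameters; gradients with respect to shift and scale
    are returned to the caller (they belong to the code generator).
    """

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: np.ndarray, shift: np.ndarray, scale: np.ndarray):
        if shift.shape[-1] != x.shape[1] or scale.shape[-1] != x.shape[1]:
            raise ValueError(
                f"code length {shift.shape[-1]}/{scale.shape[-1]} does not match "
                f"{x.shape[1]} channels")
        mu, u, s = _channel_stats(x, self.eps)
        xhat = u / s
        y = scale[None, :, None, None] * xhat + shift[None, :, None, None]
        return y, (u, s, xhat, scale)

    def backward(self, dy: np.ndarray, cache):
        u, s, xhat, scale = cache
        dshift = dy.sum(axis=(0, 2, 3))
        dscale = (dy * xhat).sum(axis=(0, 2, 3))
        dxhat = dy * scale[None, :, None, None]
        return _norm_backward(dxhat, u, s, self.eps), dshift, dscale


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache, accumulate: bool = True):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, cache, accumulate: bool = True):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache, accumulate: bool = True):
        return dy * (1.0 - cache * cache)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, dy, cache, accumulate: bool = True):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 init_std: float | None = None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        std = init_std if init_std is not None else 1.0 / np.sqrt(nin)
        self.p["W"] = (rng.standard_normal((nout, nin)) * std).astype(dtype)
        self.p["b"] = np.zeros(nout, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray):
        return x @ self.p["W"].T + self.p["b"], x

    def backward(self, dy: np.ndarray, cache, accumulate: bool = True):
        x = cache
        if accumulate:
            self.g["W"] += (dy.T @ x).astype(self.p["W"].dtype)
            self.g["b"] += dy.sum(axis=0).astype(self.p["b"].dtype)
        return dy @ self.p["W"]


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr: float = 2e-4, betas=(0.5, 0.999),
                 eps: float = 1e-8):
        self.layers = [ly for ly in layers if ly.p]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.p.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.p.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, param in ly.p.items():
                grad = ly.g[k]
                m[k] = b1 * m[k] + (1 - b1) * grad
                v[k] = b2 * v[k] + (1 - b2) * grad * grad
                mhat = m[k] / bias1
                vhat = v[k] / bias2
                param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(param.dtype)

    def zero_grad(self) -> None:
        for ly in self.layers:
            ly.zero_grad()
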