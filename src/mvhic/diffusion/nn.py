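"""Minimal numpy neural-network layers with explicit backprop.

Provides just what the conditional denoiser needs: 3x3 same-padding
convolutions (im2col + BLAS matmul), linear layers, FiLM time conditioning,
ReLU, and Adam.  Parameters and gradients live in flat name->array dicts so
the optimizer and checkpoints stay trivial.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "Linear", "FiLM", "relu", "relu_backward", "Adam", "time_embedding"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*9) patches of the 1-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (B, C, H, W, 3, 3) -> (B, H*W, C*9)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * 9)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, scale: float | None = None):
        fan_in = c_in * 9
        scale = np.sqrt(2.0 / fan_in) if scale is None else scale
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray):
        b, c, h, w = x.shape
        cols = _im2col(x)  # (B, HW, C*9)
        wmat = self.W.reshape(self.c_out, -1)  # (O, C*9)
        y = cols @ wmat.T + self.b  # (B, HW, O)
        y = y.transpose(0, 2, 1).reshape(b, self.c_out, h, w)
        return y, (cols, x.shape)

    def backward(self, dy: np.ndarray, cache):
        cols, xshape = cache
        b, c, h, w = xshape
        dyf = dy.reshape(b, self.c_out, h * w).transpose(0, 2, 1)  # (B, HW, O)
        dW = np.einsum("bpo,bpk->ok", dyf, cols).reshape(self.W.shape)
        db = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.reshape(self.c_out, -1)  # (B, HW, C*9)
        # col2im: scatter patch gradients back onto the padded input
        dxp = np.zeros((b, c, h + 2, w + 2))
        dcols = dcols.reshape(b, h, w, c, 3, 3)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        dx = dxp[:, :, 1 : 1 + h, 1 : 1 + w]
        return dx, {"W": dW, "b": db}

    def params(self):
        return {"W": self.W, "b": self.b}


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: float | None = None):
        scale = np.sqrt(1.0 / n_in) if scale is None else scale
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, dy: np.ndarray, cache):
        x = cache
        return dy @ self.W.T, {"W": x.T @ dy, "b": dy.sum(axis=0)}

    def params(self):
        return {"W": self.W, "b": self.b}


class FiLM:
    """Feature-wise affine modulation from a time embedding.

    y = x * (1 + gamma(e)) + beta(e) with per-channel gamma, beta produced by
    linear maps of the embedding; gamma is zero-initialized so the layer
    starts as the identity.
    """

    def __init__(self, emb_dim: int, channels: int, rng: np.random.Generator):
        self.gamma = Linear(emb_dim, channels, rng, scale=1e-3)
        self.beta = Linear(emb_dim, channels, rng, scale=1e-3)

    def forward(self, x: np.ndarray, emb: np.ndarray):
        g, gc = self.gamma.forward(emb)
        b_, bc = self.beta.forward(emb)
        y = x * (1.0 + g)[:, :, None, None] + b_[:, :, None, None]
        return y, (x, g, gc, bc)

    def backward(self, dy: np.ndarray, cache):
        x, g, gc, bc = cache
        dx = dy * (1.0 + g)[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        db = dy.sum(axis=(2, 3))
        demb_g, gg = self.gamma.backward(dg, gc)
        demb_b, gb = self.beta.backward(db, bc)
        grads = {f"gamma.{k}": v for k, v in gg.items()}
        grads.update({f"beta.{k}": v for k, v in gb.items()})
        return dx, demb_g + demb_b, grads

    def params(self):
        out = {f"gamma.{k}": v for k, v in self.gamma.params().items()}
        out.update({f"beta.{k}": v for k, v in self.beta.params().items()})
        return out


def relu(x: np.ndarray):
    return np.maximum(x, 0.0), x > 0


def relu_backward(dy: np.ndarray, mask: np.ndarray):
    return dy * mask


def time_embedding(t_frac: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of normalized timestep t/T in [0, 1]; (B, dim)."""
    t_frac = np.atleast_1d(np.asarray(t_frac, dtype=float))
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    args = t_frac[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
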