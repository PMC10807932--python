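"""Compact numpy U-Net with analytic backpropagation.

Encoder/decoder with five resolution levels and skip concatenation.  The 2D
variant uses 3x3 kernels, instance normalization and PReLU; the 3D variant
uses 5x5x5 kernels and batch normalization, and accepts a 2-channel input
(image + preliminary mask).  Convolutions are evaluated by summing shifted
slices over kernel offsets, which keeps memory flat for 3D kernels; all
layers implement forward/backward in closed form and are trained with Adam.

Spatial input sizes must be divisible by 2**(levels-1) so the pooling ladder
stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["UNetConfig", "UNet", "build_unet", "Adam"]


# ---------------------------------------------------------------------------
# layers: x has shape (B, C, *spatial)


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvNd(_Layer):
    """Stride-1, same-padding convolution for dim in {2, 3}."""

    def __init__(self, dim, c_in, c_out, k, rng):
        super().__init__()
        self.dim, self.k = dim, k
        fan_in = c_in * k**dim
        w_shape = (c_out, c_in) + (k,) * dim
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), w_shape)
        self.params["b"] = np.zeros(c_out)

    def _pad(self, x):
        p = self.k // 2
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.dim
        return np.pad(x, pad)

    def forward(self, x):
        self.x_pad = self._pad(x)
        w, b = self.params["w"], self.params["b"]
        spatial = x.shape[2:]
        out = np.zeros((x.shape[0], w.shape[0]) + spatial)
        for off in product(range(self.k), repeat=self.dim):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial))
            out += np.einsum("oc,bc...->bo...", w[(slice(None), slice(None)) + off],
                             self.x_pad[sl])
        return out + b.reshape((1, -1) + (1,) * self.dim)

    def backward(self, dy):
        w = self.params["w"]
        spatial = dy.shape[2:]
        dw = np.zeros_like(w)
        dx_pad = np.zeros_like(self.x_pad)
        for off in product(range(self.k), repeat=self.dim):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial))
            woff = (slice(None), slice(None)) + off
            red = (0,) + tuple(range(2, dy.ndim))
            dw[woff] = np.tensordot(dy, self.x_pad[sl], axes=(red, red))
            dx_pad[sl] += np.einsum("oc,bo...->bc...", w[woff], dy)
        self.grads["w"] = dw
        self.grads["b"] = dy.sum(axis=(0,) + tuple(range(2, dy.ndim)))
        p = self.k // 2
        crop = (slice(None), slice(None)) + tuple(slice(p, d - p) for d in dx_pad.shape[2:])
        return dx_pad[crop]


class _Norm(_Layer):
    """Instance norm (axes = spatial) or batch norm (axes = batch + spatial)."""

    def __init__(self, dim, channels, kind):
        super().__init__()
        self.kind = kind
        self.spatial_axes = tuple(range(2, 2 + dim))
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.eps = 1e-5

    def _axes(self):
        return self.spatial_axes if self.kind == "instance" else (0,) + self.spatial_axes

    def forward(self, x):
        axes = self._axes()
        self.mu = x.mean(axis=axes, keepdims=True)
        self.var = x.var(axis=axes, keepdims=True)
        self.xhat = (x - self.mu) / np.sqrt(self.var + self.eps)
        shape = (1, -1) + (1,) * len(self.spatial_axes)
        return self.params["gamma"].reshape(shape) * self.xhat + \
            self.params["beta"].reshape(shape)

    def backward(self, dy):
        axes = self._axes()
        shape = (1, -1) + (1,) * len(self.spatial_axes)
        g = self.params["gamma"].reshape(shape)
        red = (0,) + self.spatial_axes
        self.grads["gamma"] = (dy * self.xhat).sum(axis=red)
        self.grads["beta"] = dy.sum(axis=red)
        n = np.prod([dy.shape[a] for a in axes])
        dxhat = dy * g
        inv_sd = 1.0 / np.sqrt(self.var + self.eps)
        return (inv_sd / n) * (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - self.xhat * (dxhat * self.xhat).sum(axis=axes, keepdims=True)
        )


class PReLU(_Layer):
    def __init__(self, channels, init=0.25):
        super().__init__()
        self.params["a"] = np.full(channels, init)

    def forward(self, x):
        self.x = x
        shape = (1, -1) + (1,) * (x.ndim - 2)
        a = self.params["a"].reshape(shape)
        return np.where(x > 0, x, a * x)

    def backward(self, dy):
        shape = (1, -1) + (1,) * (dy.ndim - 2)
        a = self.params["a"].reshape(shape)
        neg = self.x <= 0
        self.grads["a"] = (dy * self.x * neg).sum(
            axis=(0,) + tuple(range(2, dy.ndim)))
        return np.where(neg, a * dy, dy)


class MaxPool2(_Layer):
    """Factor-2 max pooling over every spatial axis."""

    def forward(self, x):
        self.in_shape = x.shape
        dim = x.ndim - 2
        shape = list(x.shape[:2])
        for s in x.shape[2:]:
            if s % 2:
                raise ValueError("spatial size must be even for pooling")
            shape += [s // 2, 2]
        xr = x.reshape(shape)
        axes = tuple(3 + 2 * i for i in range(dim))
        out = xr.max(axis=axes)
        expand = out
        for a in axes:
            expand = np.expand_dims(expand, a)
        mask = (xr == expand)
        self.mask = mask / np.maximum(mask.sum(axis=axes, keepdims=True), 1)
        return out

    def backward(self, dy):
        dim = dy.ndim - 2
        axes = tuple(3 + 2 * i for i in range(dim))
        expand = dy
        for a in axes:
            expand = np.expand_dims(expand, a)
        return (self.mask * expand).reshape(self.in_shape)


class UpsampleNearest2(_Layer):
    def forward(self, x):
        for a in range(2, x.ndim):
            x = np.repeat(x, 2, axis=a)
        return x

    def backward(self, dy):
        dim = dy.ndim - 2
        shape = list(dy.shape[:2])
        for s in dy.shape[2:]:
            shape += [s // 2, 2]
        axes = tuple(3 + 2 * i for i in range(dim))
        return dy.reshape(shape).sum(axis=axes)


# ---------------------------------------------------------------------------
# model


@dataclass
class UNetConfig:
    """Architecture knobs; defaults follow the two stage variants.

    dim = 2: 3x3 kernels with instance norm; dim = 3: 5x5x5 kernels with
    batch norm and a 2-channel input (image + preliminary mask).
    """

    dim: int = 2
    in_channels: int | None = None
    base_width: int = 8
    levels: int = 5
    kernel: int | None = None
    norm: str | None = None
    width_growth: tuple[int, ...] = (1, 2, 4, 4, 4)

    def resolved(self) -> "UNetConfig":
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")
        cfg = UNetConfig(
            dim=self.dim,
            in_channels=self.in_channels or (1 if self.dim == 2 else 2),
            base_width=self.base_width,
            levels=self.levels,
            kernel=self.kernel or (3 if self.dim == 2 else 5),
            norm=self.norm or ("instance" if self.dim == 2 else "batch"),
            width_growth=self.width_growth,
        )
        if cfg.norm not in ("instance", "batch"):
            raise ValueError("norm must be 'instance' or 'batch'")
        return cfg


class _ConvBlock(_Layer):
    def __init__(self, dim, c_in, c_out, k, norm, rng):
        super().__init__()
        self.layers = [ConvNd(dim, c_in, c_out, k, rng), _Norm(dim, c_out, norm),
                       PReLU(c_out)]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Five-level encoder/decoder with skip concatenation and a 1-channel
    sigmoid foreground head."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = cfg = config.resolved()
        rng = np.random.default_rng(seed)
        growth = list(cfg.width_growth) + [cfg.width_growth[-1]] * cfg.levels
        widths = [cfg.base_width * growth[i] for i in range(cfg.levels)]
        self.widths = widths
        d, k, nm = cfg.dim, cfg.kernel, cfg.norm
        self.enc = []
        c = cfg.in_channels
        for w in widths:
            self.enc.append(_ConvBlock(d, c, w, k, nm, rng))
            c = w
        self.pools = [MaxPool2() for _ in range(cfg.levels - 1)]
        self.ups = [UpsampleNearest2() for _ in range(cfg.levels - 1)]
        self.dec = []
        for lvl in range(cfg.levels - 2, -1, -1):
            c_in = widths[lvl + 1] + widths[lvl]  # upsampled + skip
            self.dec.append(_ConvBlock(d, c_in, widths[lvl], k, nm, rng))
        self.head = ConvNd(d, widths[0], 1, 1, rng)

    # -- plumbing -----------------------------------------------------------

    def _check_input(self, x):
        cfg = self.config
        if x.ndim != cfg.dim + 2 or x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected (B, {cfg.in_channels}, {'x'.join(['S'] * cfg.dim)}), "
                f"got {x.shape}")
        div = 2 ** (cfg.levels - 1)
        for s in x.shape[2:]:
            if s % div:
                raise ValueError(f"spatial sizes must be divisible by {div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of the foreground channel, same spatial size as the input."""
        self._check_input(x)
        skips = []
        for lvl, block in enumerate(self.enc):
            x = block.forward(x)
            if lvl < len(self.pools):
                skips.append(x)
                x = self.pools[lvl].forward(x)
        self._skip_channels = []
        for i, block in enumerate(self.dec):
            x = self.ups[i].forward(x)
            skip = skips.pop()
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        d_skips = []
        for i in range(len(self.dec) - 1, -1, -1):
            dy = self.dec[i].backward(dy)
            c_up, _ = self._skip_channels[i]
            d_up, d_skip = dy[:, :c_up], dy[:, c_up:]
            d_skips.append(d_skip)
            dy = self.ups[i].backward(d_up)
        d_skips.reverse()  # d_skips[i] pairs with enc level (levels-2-i)
        for lvl in range(len(self.enc) - 1, -1, -1):
            if lvl < len(self.pools):
                dy = self.pools[lvl].backward(dy)
                dy = dy + d_skips[len(self.dec) - 1 - lvl]
            dy = self.enc[lvl].backward(dy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward(x)))

    # -- parameters ---------------------------------------------------------

    def _layers(self):
        out = []
        for b in self.enc + self.dec:
            out.extend(b.layers)
        out.append(self.head)
        return out

    def parameters(self):
        """List of (layer, name) pairs for every trainable array."""
        return [(l, k) for l in self._layers() for k in l.params]

    def n_parameters(self) -> int:
        return sum(l.params[k].size for l, k in self.parameters())

    def describe(self) -> dict:
        cfg = self.config
        return {
            "dim": cfg.dim,
            "in_channels": cfg.in_channels,
            "levels": cfg.levels,
            "kernel": cfg.kernel,
            "norm": cfg.norm,
            "widths": self.widths,
            "n_parameters": self.n_parameters(),
        }


def build_unet(dim: int, config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Assemble a U-Net variant: 2D (3x3 kernels, instance norm, 1-channel
    input) or 3D (5x5x5 kernels, batch norm, 2-channel input)."""
    cfg = config or UNetConfig()
    cfg = UNetConfig(**{**cfg.__dict__, "dim": dim})
    return UNet(cfg, seed=seed)


class Adam:
    def __init__(self, model: UNet, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model, self.lr, self.betas, self.eps = model, lr, betas, eps
        self.state = {}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for l, k in self.model.parameters():
            g = l.grads.get(k)
            if g is None:
                continue
            key = (id(l), k)
            m, v = self.state.get(key, (np.zeros_like(g), np.zeros_like(g)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.state[key] = (m, v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            l.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
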