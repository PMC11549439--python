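"""A compact 2D U-Net implemented directly on NumPy.

The network follows the segmentation architecture used for the serial-section
dataset: three encoder blocks (two 3x3 convolutions each, 8/16/32 features,
batch normalisation, dropout before each 2x2 max pooling), a 64-feature
bottleneck with a 2x2 transpose convolution, a mirrored decoder with skip
concatenations, and a 3x3 output convolution to 2 classes under a softmax.
All convolutions use ReLU activations.

Everything — im2col convolution, batch norm, pooling, transpose convolution,
softmax cross-entropy and the Adam optimizer — is written out explicitly so
the package has no framework dependency.  Training is single-threaded and
fully deterministic under a fixed seed.  This is a desk-scale engine: it is
meant for tiles of order 128 px, not the 20k-px originals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``tile_size`` must be divisible by 8 (three 2x2 poolings).
    ``downsample_factor`` is 1 for five structures and 4 for the olfactory
    bulb, whose large-scale shape is better learned at 4.39 µm/px.
    """

    tile_size: int = 512
    in_channels: int = 4
    encoder_features: tuple[int, ...] = (8, 16, 32)
    bottleneck_features: int = 64
    dropout: float = 0.2
    out_classes: int = 2
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        divisor = 2 ** len(self.encoder_features)
        if self.tile_size % divisor != 0:
            raise ValueError(
                f"tile_size {self.tile_size} must be divisible by {divisor}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# layers


class Layer:
    def params(self):  # -> dict name -> array
        return {}

    def grads(self):
        return {}


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, c_in, c_out, k=3, rng=None):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU nets
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        self._cols, self._shape = cols, (n, c, h, w)
        out = cols @ self.W.reshape(self.c_out, -1).T + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g):
        n, c, h, w = self._shape
        p, k = self.k // 2, self.k
        gm = g.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW[...] = (gm.T @ self._cols).reshape(self.W.shape)
        self.db[...] = gm.sum(axis=0)
        dcols = (gm @ self.W.reshape(self.c_out, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def n_params(self):
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, training=False):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


class BatchNorm2d(Layer):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._std = std
        self._training = training
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        xhat, std = self._xhat, self._std
        self.dgamma[...] = (g * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = g.sum(axis=(0, 2, 3))
        gs = g * self.gamma[None, :, None, None]
        if not self._training:
            return gs / std[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        t1 = gs - gs.mean(axis=(0, 2, 3))[None, :, None, None]
        t2 = xhat * (gs * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        dx = (t1 - t2) / std[None, :, None, None]
        self._xhat = None
        return dx

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"run_mean": self.run_mean, "run_var": self.run_var}

    def n_params(self):
        return self.gamma.size + self.beta.size


class MaxPool2(Layer):
    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # distribute across ties so the operator stays a valid subgradient
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._shape = (n, c, h, w)
        return out

    def backward(self, g):
        n, c, h, w = self._shape
        gx = self._mask * g[:, :, :, None, :, None]
        self._mask = None
        return gx.reshape(n, c, h, w).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; the mask stream is owned by the parent network."""

    def __init__(self, p, rng):
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._m = None
            return x
        self._m = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._m

    def backward(self, g):
        return g if self._m is None else g * self._m


class ConvTranspose2(Layer):
    """2x2 transpose convolution with stride 2 (learned upsampling)."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.W = (rng.standard_normal((c_in, c_out, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_out = c_out

    def forward(self, x, training=False):
        self._x = x
        n, c, h, w = x.shape
        out = np.einsum("nihw,iokl->nohkwl", x, self.W, optimize=True)
        out = out.reshape(n, self.c_out, 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, g):
        n = g.shape[0]
        h2, w2 = g.shape[2], g.shape[3]
        gr = g.reshape(n, self.c_out, h2 // 2, 2, w2 // 2, 2)
        self.dW[...] = np.einsum("nihw,nohkwl->iokl", self._x, gr, optimize=True)
        self.db[...] = g.sum(axis=(0, 2, 3))
        dx = np.einsum("nohkwl,iokl->nihw", gr, self.W, optimize=True)
        self._x = None
        return dx.astype(np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def n_params(self):
        return self.W.size + self.b.size


# ---------------------------------------------------------------------------
# the network


class _ConvBlock:
    """Two 3x3 conv+ReLU, then batch normalisation."""

    def __init__(self, c_in, c_mid, rng):
        self.layers = [
            Conv2d(c_in, c_mid, rng=rng),
            ReLU(),
            Conv2d(c_mid, c_mid, rng=rng),
            ReLU(),
            BatchNorm2d(c_mid),
        ]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet:
    """The serial-section segmentation network (2 output classes, softmax)."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(seed + 10_000)
        f = config.encoder_features
        fb = config.bottleneck_features
        cin = config.in_channels

        self.enc = []
        prev = cin
        for feats in f:
            self.enc.append(
                {
                    "block": _ConvBlock(prev, feats, rng),
                    "drop": Dropout(config.dropout, self._drop_rng),
                    "pool": MaxPool2(),
                }
            )
            prev = feats
        self.bottleneck = _ConvBlock(prev, fb, rng)
        self.up = []
        self.dec = []
        prev = fb
        for feats in reversed(f):
            self.up.append(ConvTranspose2(prev, feats, rng))
            self.dec.append(_ConvBlock(2 * feats, feats, rng))
            prev = feats
        self.out_conv = Conv2d(prev, config.out_classes, rng=rng)

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        for i, e in enumerate(self.enc):
            for j, l in enumerate(e["block"].layers):
                yield f"enc{i}.{j}", l
        for j, l in enumerate(self.bottleneck.layers):
            yield f"bott.{j}", l
        for i, (u, d) in enumerate(zip(self.up, self.dec)):
            yield f"up{i}", u
            for j, l in enumerate(d.layers):
                yield f"dec{i}.{j}", l
        yield "out", self.out_conv

    def parameters(self):
        out = {}
        for name, mod in self._modules():
            for pname, arr in mod.params().items():
                out[f"{name}.{pname}"] = arr
        return out

    def gradients(self):
        out = {}
        for name, mod in self._modules():
            for pname, arr in mod.grads().items():
                out[f"{name}.{pname}"] = arr
        return out

    def num_params(self) -> int:
        return sum(int(a.size) for a in self.parameters().values())

    def state_dict(self):
        state = dict(self.parameters())
        for name, mod in self._modules():
            if isinstance(mod, BatchNorm2d):
                for sname, arr in mod.state().items():
                    state[f"{name}.{sname}"] = arr
        return {k: v.copy() for k, v in state.items()}

    def load_state_dict(self, state):
        live = dict(self.parameters())
        for name, mod in self._modules():
            if isinstance(mod, BatchNorm2d):
                for sname, arr in mod.state().items():
                    live[f"{name}.{sname}"] = arr
        for k, v in state.items():
            live[k][...] = v

    # -- forward / backward -------------------------------------------------
    def forward(self, x, training=False):
        """x: (N, C, H, W) float32 -> class probabilities (N, 2, H, W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for e in self.enc:
            x = e["block"].forward(x, training)
            skips.append(x)  # skip taken before pooling
            x = e["drop"].forward(x, training)
            x = e["pool"].forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for u, d, skip in zip(self.up, self.dec, reversed(skips)):
            x = u.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = d.forward(x, training)
        logits = self.out_conv.forward(x, training)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward_from_loss(self, target):
        """Backprop of softmax cross-entropy; ``target`` is (N, H, W) {0,1}."""
        p = self._probs
        n, _, h, w = p.shape
        onehot = np.zeros_like(p)
        onehot[:, 1][target > 0.5] = 1.0
        onehot[:, 0][target <= 0.5] = 1.0
        g = (p - onehot) / (n * h * w)
        g = self.out_conv.backward(g.astype(np.float32))
        skip_grads = []
        for u, d, cs in zip(
            reversed(self.up), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = d.backward(g)
            skip_grads.append(g[:, :cs])
            g = u.backward(g[:, cs:])
        g = self.bottleneck.backward(g)
        for e, gs in zip(reversed(self.enc), reversed(skip_grads)):
            g = e["pool"].backward(g)
            g = e["drop"].backward(g)
            g = e["block"].backward(g + gs)
        return g

    def predict_proba(self, x):
        """Foreground probability map(s); x (C,H,W) or (N,C,H,W)."""
        single = x.ndim == 3
        if single:
            x = x[None]
        p = self.forward(x, training=False)[:, 1]
        return p[0] if single else p


def cross_entropy(probs, target, eps=1e-7):
    """Mean per-pixel binary cross-entropy of the foreground probability."""
    p1 = np.clip(probs[:, 1] if probs.ndim == 4 else probs, eps, 1 - eps)
    t = (np.asarray(target) > 0.5).astype(np.float32)
    return float(-np.mean(t * np.log(p1) + (1 - t) * np.log(1 - p1)))


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, net: UNet, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in net.parameters().items()}
        self.v = {k: np.zeros_like(v) for k, v in net.parameters().items()}
        self.t = 0

    def step(self):
        self.t += 1
        params = self.net.parameters()
        grads = self.net.gradients()
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
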