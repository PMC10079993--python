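"""NumPy layers with explicit forward/backward passes.

Tensors are (batch, channels, height, width) throughout. Convolutions act
along the width axis only (the temporal axis of an EEG epoch, or a matrix
row of a connectivity image) except for the depthwise *spatial* convolution,
which collapses the height (electrode) axis. The network is small enough
(~1.7k parameters) that plain einsum/stride-trick implementations are fast
on one CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameter dicts plus cached-activation backward pass."""

    name = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: parameter names subject to weight decay (weights yes, biases and
        #: normalization parameters no)
        self.decay: set[str] = set()

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def apply_constraints(self) -> None:
        """Projection step after a parameter update (e.g. max-norm)."""

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ConvWidth(Layer):
    """Grouped convolution along the width axis, symmetric zero padding.

    Weight shape (out_ch, in_ch // groups, kernel). With an even kernel and
    padding = kernel // 2 the output is one sample wider than the input
    (cross-correlation convention).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int = 0,
                 groups: int = 1, bias: bool = False, *,
                 rng: np.random.Generator, name: str = "conv") -> None:
        super().__init__()
        assert in_ch % groups == 0 and out_ch % groups == 0
        self.name = name
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.pad, self.groups = kernel, pad, groups
        cg = in_ch // groups
        fan_in = cg * kernel
        fan_out = (out_ch // groups) * kernel
        self.params["weight"] = _glorot_uniform(
            rng, (out_ch, cg, kernel), fan_in, fan_out)
        self.decay.add("weight")
        if bias:
            self.params["bias"] = np.zeros(out_ch)

    def _fft_threshold(self, w_out: int) -> bool:
        # im2col materializes Wo * K taps per input sample; beyond this the
        # FFT path is both faster and lighter
        return self.kernel * w_out >= 8192

    def _forward_fft(self, x: np.ndarray) -> np.ndarray:
        from scipy import fft as sfft

        g, og, cg = self.groups, self.out_ch // self.groups, self.in_ch // self.groups
        k = self.kernel
        if self.pad:
            x = np.pad(x, [(0, 0), (0, 0), (0, 0), (self.pad, self.pad)])
        n, _, h, wp = x.shape
        wo = wp - k + 1
        L = sfft.next_fast_len(wp + k - 1)
        xf = sfft.rfft(x, L, axis=-1).reshape(n, g, cg, h, -1)
        wf = sfft.rfft(self.params["weight"][:, :, ::-1], L, axis=-1)
        wf = wf.reshape(g, og, cg, -1)
        yf = np.einsum("ngchf,gocf->ngohf", xf, wf, optimize=True)
        y = sfft.irfft(yf.reshape(n, self.out_ch, h, -1), L, axis=-1)
        out = y[..., k - 1:k - 1 + wo].copy()
        if "bias" in self.params:
            out += self.params["bias"][None, :, None, None]
        self._xf, self._L, self._wp = xf, L, wp
        return out

    def _backward_fft(self, gout: np.ndarray) -> np.ndarray:
        from scipy import fft as sfft

        g, og, cg = self.groups, self.out_ch // self.groups, self.in_ch // self.groups
        k, L, wp = self.kernel, self._L, self._wp
        n, _, h, wo = gout.shape
        gf = sfft.rfft(gout, L, axis=-1).reshape(n, g, og, h, -1)
        grf = sfft.rfft(gout[..., ::-1], L, axis=-1).reshape(n, g, og, h, -1)
        # dL/dw = correlation of padded input with gout
        gwf = np.einsum("ngchf,ngohf->gocf", self._xf, grf, optimize=True)
        gw = sfft.irfft(gwf.reshape(self.out_ch, cg, -1), L, axis=-1)
        self.grads["weight"] = gw[..., wo - 1:wo - 1 + k].copy()
        if "bias" in self.params:
            self.grads["bias"] = gout.sum(axis=(0, 2, 3))
        # dL/dx_padded = plain convolution of gout with the kernel
        wf = sfft.rfft(self.params["weight"], L, axis=-1).reshape(g, og, cg, -1)
        gxf = np.einsum("ngohf,gocf->ngchf", gf, wf, optimize=True)
        gx = sfft.irfft(gxf.reshape(n, self.in_ch, h, -1), L, axis=-1)[..., :wp]
        if self.pad:
            gx = gx[..., self.pad:wp - self.pad]
        return np.ascontiguousarray(gx)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(g, N*H*Wo, Cg*K) contiguous column matrix of sliding windows."""
        if self.pad:
            x = np.pad(x, [(0, 0), (0, 0), (0, 0), (self.pad, self.pad)])
        win = sliding_window_view(x, self.kernel, axis=-1)  # (N, C, H, Wo, K)
        n, _, h, wo, k = win.shape
        g, cg = self.groups, self.in_ch // self.groups
        win = win.reshape(n, g, cg, h, wo, k)
        # -> (g, N, H, Wo, Cg, K); matmul needs contiguity, so copy once
        col = np.ascontiguousarray(win.transpose(1, 0, 3, 4, 2, 5))
        self._nhw = (n, h, wo)
        return col.reshape(g, n * h * wo, cg * k)

    def forward(self, x, training=False, rng=None):
        wo = x.shape[-1] + 2 * self.pad - self.kernel + 1
        self._fft = self._fft_threshold(wo)
        if self._fft:
            self._w_in = x.shape[-1]
            return self._forward_fft(x)
        g, og = self.groups, self.out_ch // self.groups
        col = self._im2col(x)
        w = self.params["weight"].reshape(g, og, -1)  # (g, Og, Cg*K)
        out = col @ w.transpose(0, 2, 1)  # (g, N*H*Wo, Og)
        n, h, wo = self._nhw
        out = out.reshape(g, n, h, wo, og).transpose(1, 0, 4, 2, 3)
        out = np.ascontiguousarray(out).reshape(n, self.out_ch, h, wo)
        if "bias" in self.params:
            out += self.params["bias"][None, :, None, None]
        self._col = col
        self._w_in = x.shape[-1]
        return out

    def backward(self, gout):
        if self._fft:
            return self._backward_fft(gout)
        g, og, cg = self.groups, self.out_ch // self.groups, self.in_ch // self.groups
        k = self.kernel
        n, _, h, wo = gout.shape
        g_g = gout.reshape(n, g, og, h, wo).transpose(1, 2, 0, 3, 4)
        g_g = np.ascontiguousarray(g_g).reshape(g, og, n * h * wo)
        gw = g_g @ self._col  # (g, Og, Cg*K)
        self.grads["weight"] = gw.reshape(self.out_ch, cg, k)
        if "bias" in self.params:
            self.grads["bias"] = gout.sum(axis=(0, 2, 3))
        w = self.params["weight"].reshape(g, og, cg * k)
        gcol = g_g.transpose(0, 2, 1) @ w  # (g, N*H*Wo, Cg*K)
        gcol = gcol.reshape(g, n, h, wo, cg, k).transpose(1, 0, 4, 2, 3, 5)
        gcol = gcol.reshape(n, self.in_ch, h, wo, k)
        # col2im: scatter-add each kernel tap back onto the padded input grid
        wp = self._w_in + 2 * self.pad
        gx = np.zeros((n, self.in_ch, h, wp))
        for tap in range(k):
            gx[..., tap:tap + wo] += gcol[..., tap]
        if self.pad:
            gx = gx[..., self.pad:wp - self.pad]
        return gx


class SpatialDepthwiseConv(Layer):
    """Depthwise convolution over the full electrode (height) axis.

    Each of the in_ch temporal feature maps learns `mult` spatial filters
    spanning all electrodes, collapsing height to 1; an L2 max-norm
    constraint on each spatial filter regularizes it (compact-CNN
    convention).
    """

    def __init__(self, in_ch: int, mult: int, height: int,
                 max_norm: float = 1.0, *, rng: np.random.Generator,
                 name: str = "spatial_conv") -> None:
        super().__init__()
        self.name = name
        self.in_ch, self.mult, self.height = in_ch, mult, height
        self.max_norm = max_norm
        self.params["weight"] = _glorot_uniform(
            rng, (in_ch, mult, height), height, height)
        self.decay.add("weight")

    def forward(self, x, training=False, rng=None):
        self._x = x
        out = np.einsum("cmh,nchw->ncmw", self.params["weight"], x,
                        optimize=True)
        n, c, m, w = out.shape
        return out.reshape(n, c * m, 1, w)

    def backward(self, gout):
        n = gout.shape[0]
        g = gout.reshape(n, self.in_ch, self.mult, gout.shape[-1])
        self.grads["weight"] = np.einsum("ncmw,nchw->cmh", g, self._x,
                                         optimize=True)
        return np.einsum("ncmw,cmh->nchw", g, self.params["weight"],
                         optimize=True)

    def apply_constraints(self):
        w = self.params["weight"]
        norms = np.linalg.norm(w, axis=-1, keepdims=True)
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.params["weight"] = w * factor


class BatchNorm(Layer):
    """Batch normalization over (batch, height, width) per channel."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        super().__init__()
        self.name = name
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_ch)
        self.params["beta"] = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x, training=False, rng=None):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._training = xhat, inv, training
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, gout):
        axes = (0, 2, 3)
        self.grads["gamma"] = (gout * self._xhat).sum(axis=axes)
        self.grads["beta"] = gout.sum(axis=axes)
        gam_inv = (self.params["gamma"] * self._inv)[None, :, None, None]
        if not self._training:
            return gout * gam_inv
        n = gout.shape[0] * gout.shape[2] * gout.shape[3]
        mean_g = gout.mean(axis=axes, keepdims=True)
        mean_gx = (gout * self._xhat).mean(axis=axes, keepdims=True)
        return gam_inv * (gout - mean_g - self._xhat * mean_gx)


class ELU(Layer):
    name = "elu"

    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        self._y_neg = neg
        self._pos = x > 0
        return np.where(self._pos, x, neg)

    def backward(self, gout):
        return gout * np.where(self._pos, 1.0, self._y_neg + self.alpha)


class AvgPoolWidth(Layer):
    """Non-overlapping average pooling along width (tail remainder dropped)."""

    def __init__(self, k: int, name: str = "avgpool") -> None:
        super().__init__()
        self.name = name
        self.k = k

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        wo = w // self.k
        self._w_in = w
        return x[..., :wo * self.k].reshape(n, c, h, wo, self.k).mean(axis=-1)

    def backward(self, gout):
        n, c, h, wo = gout.shape
        gx = np.zeros((n, c, h, self._w_in))
        gx[..., :wo * self.k] = np.repeat(gout / self.k, self.k, axis=-1)
        return gx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    name = "dropout"

    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class LogSoftmax(Layer):
    """Log-softmax over the class axis of (batch, classes)."""

    name = "log_softmax"

    def forward(self, x, training=False, rng=None):
        z = x - x.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        self._p = np.exp(logp)
        return logp

    def backward(self, gout):
        return gout - self._p * gout.sum(axis=1, keepdims=True)
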