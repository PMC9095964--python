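"""Convolutional encoder-decoder networks and the Adam optimizer.

Both networks used by the cascade follow the same U-shaped layout: one
convolution per scale with the channel widths given as a symmetric list
(e.g. ``[32, 64, 128, 256, 128, 64, 32]``), 2x max-pooling between encoder
scales, transposed-convolution upsampling with skip concatenation between
decoder scales, leaky-ReLU activations, and a final convolution with no
activation.  The final layer can be zero-initialized so that the network
starts as the zero map (identity motion / identity residual).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["UNet", "Adam", "he_uniform"]


def he_uniform(rng, shape, fan_in, dtype=np.float32):
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class UNet:
    """U-shaped encoder-decoder over 2 or 3 spatial dimensions.

    Parameters
    ----------
    in_channels, out_channels : int
        Channel counts of the input stack and the prediction.
    channels : sequence of int
        Symmetric width list; its length must be odd.  ``(len-1)//2``
        pooling levels are used.
    ndim : {2, 3}
        Spatial dimensionality (3 treats the frame axis as a third
        spatial-like axis).
    """

    def __init__(self, in_channels, out_channels, channels, ndim=2,
                 leaky_slope=0.01, zero_init_final=True, kernel=3, seed=0):
        channels = list(channels)
        if len(channels) % 2 != 1:
            raise ValueError("channel list length must be odd")
        if channels != channels[::-1]:
            raise ValueError("channel list must be symmetric")
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.channels = channels
        self.ndim = ndim
        self.leaky_slope = leaky_slope
        self.kernel = kernel
        self.depth = (len(channels) - 1) // 2
        rng = np.random.default_rng(seed)

        kvol = kernel ** ndim
        kshape = (kernel,) * ndim
        self.enc_w, self.enc_b = [], []
        prev = in_channels
        for c in channels[: self.depth + 1]:
            w = Tensor(he_uniform(rng, (c, prev) + kshape, prev * kvol),
                       requires_grad=True)
            b = Tensor(np.zeros(c, np.float32), requires_grad=True)
            self.enc_w.append(w)
            self.enc_b.append(b)
            prev = c
        self.up_w, self.dec_w, self.dec_b = [], [], []
        for i, c in enumerate(channels[self.depth + 1:]):
            skip = channels[self.depth - 1 - i]
            uw = Tensor(he_uniform(rng, (prev, prev) + (2,) * ndim, prev * 2 ** ndim),
                        requires_grad=True)
            w = Tensor(he_uniform(rng, (c, prev + skip) + kshape,
                                  (prev + skip) * kvol), requires_grad=True)
            b = Tensor(np.zeros(c, np.float32), requires_grad=True)
            self.up_w.append(uw)
            self.dec_w.append(w)
            self.dec_b.append(b)
            prev = c
        if zero_init_final:
            fw = np.zeros((out_channels, prev) + kshape, np.float32)
        else:
            fw = he_uniform(rng, (out_channels, prev) + kshape, prev * kvol)
        self.final_w = Tensor(fw, requires_grad=True)
        self.final_b = Tensor(np.zeros(out_channels, np.float32),
                              requires_grad=True)

    # ------------------------------------------------------------------
    def parameters(self):
        return (self.enc_w + self.enc_b + self.up_w + self.dec_w + self.dec_b
                + [self.final_w, self.final_b])

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def _conv(self, x, w, b):
        if self.ndim == 2:
            return ad.conv2d(x, w, b, self.kernel)
        return ad.conv3d(x, w, b, self.kernel)

    def forward(self, x):
        """x: Tensor (Cin, *spatial) -> Tensor (Cout, *spatial)."""
        if x.data.shape[0] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.data.shape[0]}")
        skips = []
        h = self._conv(x, self.enc_w[0], self.enc_b[0]).leaky_relu(self.leaky_slope)
        for i in range(1, self.depth + 1):
            skips.append(h)
            h = ad.maxpool(h, self.ndim)
            h = self._conv(h, self.enc_w[i], self.enc_b[i]).leaky_relu(self.leaky_slope)
        for i in range(self.depth):
            skip = skips[-1 - i]
            h = ad.conv_transpose_up(h, self.up_w[i], self.ndim)
            h = ad.crop_to(h, skip.data.shape[1:])
            h = ad.concatenate([h, skip], axis=0)
            h = self._conv(h, self.dec_w[i], self.dec_b[i]).leaky_relu(self.leaky_slope)
        return self._conv(h, self.final_w, self.final_b)

    __call__ = forward

    # -- checkpointing --------------------------------------------------
    def state_dict(self):
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


class Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)
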