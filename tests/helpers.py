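"""Shared oracles and generators for the test suite."""

import numpy as np
from scipy.ndimage import gaussian_filter

from grdrn import diffeo


def smooth_random_fields(n, size, amplitude, seed):
    """Seeded smooth random velocity fields with peak |v| = amplitude."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 2, size, size))
    v = gaussian_filter(v, sigma=(0, 0, 6, 6))
    return v / np.abs(v).max() * amplitude


def euler_flow(v, n_sub=1000):
    """Dense forward-Euler integration of one stationary field: the
    independent oracle for unit-time flows."""
    H, W = v.shape[1:]
    gr, gc = np.meshgrid(np.arange(H, dtype=float),
                         np.arange(W, dtype=float), indexing="ij")
    pr, pc = gr.copy(), gc.copy()
    dt = 1.0 / n_sub
    for _ in range(n_sub):
        d = np.stack([pr - gr, pc - gc])
        pr = pr + dt * diffeo.warp_image(v[0], d)
        pc = pc + dt * diffeo.warp_image(v[1], d)
    return np.stack([pr - gr, pc - gc])
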