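"""Unrolled motion-augmented reconstruction cascade.

Each unrolled iteration (i) registers the current magnitude frames
groupwise to the implicit template, (ii) generates a motion-augmented
sequence by warping the template backward to every frame and enforcing
data consistency — fusing all frames' measurements into each frame —
(iii) removes residual aliasing with a 3D (2 spatial + frame) residual
network, and (iv) enforces data consistency again.  Network parameters are
shared across iterations.  With ``motion_mode="none"`` the registration
inputs are dropped, recovering the classic dealiasing + data-consistency
cascade (the motion-free ablation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import diffeo, nn
from .autodiff import Tensor
from .containers import KSpaceSequence, SamplingMask
from .registration import RegistrationNetwork, compute_template, select_reference

__all__ = ["ReconConfig", "DealiasingNetwork", "IterationState",
           "motion_augment", "dealias_step", "unrolled_forward",
           "complex_to_channels", "channels_to_complex", "magnitude_t"]


@dataclass
class ReconConfig:
    channels: tuple = (32, 64, 128, 256, 128, 64, 32)
    iterations: int = 4
    motion_mode: str = "full"          # "full" | "none" (motion-free ablation)
    shared_weights: bool = True
    use_zero_fill_branch: bool = True  # feed the zero-filled motion branch too
    phase_source: str = "zero"         # phase of the lifted template: "zero" | "previous"
    leaky_slope: float = 0.01
    zero_init_final_layer: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.motion_mode not in ("full", "none"):
            raise ValueError("motion_mode must be 'full' or 'none'")
        if self.phase_source not in ("zero", "previous"):
            raise ValueError("phase_source must be 'zero' or 'previous'")

    @property
    def in_channels(self) -> int:
        if self.motion_mode == "none":
            return 2
        return 6 if self.use_zero_fill_branch else 4


class DealiasingNetwork:
    """Residual dealiaser H_phi: a 3D encoder-decoder over real/imaginary
    channel pairs, with the frame axis as the third spatial-like axis."""

    def __init__(self, config: ReconConfig):
        self.config = config
        self.unet = nn.UNet(
            in_channels=config.in_channels,
            out_channels=2,
            channels=config.channels,
            ndim=3,
            leaky_slope=config.leaky_slope,
            zero_init_final=config.zero_init_final_layer,
            seed=config.seed + 1,
        )

    def parameters(self):
        return self.unet.parameters()


# ---------------------------------------------------------------------------
# complex <-> channel packing
# ---------------------------------------------------------------------------

def complex_to_channels(frames: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(N, H, W) complex -> (N, 2, H, W) real/imag channels."""
    frames = np.asarray(frames)
    return np.stack([frames.real, frames.imag], axis=1).astype(dtype)


def channels_to_complex(x) -> np.ndarray:
    """(N, 2, H, W) -> (N, H, W) complex."""
    d = x.data if isinstance(x, Tensor) else np.asarray(x)
    return d[:, 0] + 1j * d[:, 1]


def magnitude_t(x: Tensor, eps: float = 1e-12) -> Tensor:
    """|x| for a (N, 2, H, W) real/imag tensor -> (N, H, W)."""
    return (x.square().sum(axis=1) + eps).sqrt()


# ---------------------------------------------------------------------------
# cascade building blocks
# ---------------------------------------------------------------------------

def motion_augment(template, backward, acquired, mask, phase=None):
    """Generate motion-augmented frames G_n = DC(T_n^-1 o template).

    The real template (built from magnitudes) is warped backward to each
    frame, lifted to a complex frame — zero imaginary part by default, or
    multiplied by a supplied per-frame phase map — and passed through data
    consistency so every G_n matches the acquired data on its mask support
    exactly.

    template: (H, W) Tensor or ndarray; backward: (N, 2, H, W);
    acquired: (N, H, W) complex ndarray; mask: (N, H, W) binary ndarray;
    phase: optional (N, H, W) complex unit-modulus ndarray.
    Returns a Tensor (N, 2, H, W).
    """
    tpl = template if isinstance(template, Tensor) else Tensor(
        np.asarray(template, dtype=np.float32))
    bwd = backward if isinstance(backward, Tensor) else Tensor(
        np.asarray(backward, dtype=np.float32))
    acquired = np.asarray(acquired)
    mask = np.asarray(mask).astype(np.float64)
    n, h, w = acquired.shape
    if tpl.data.shape != (h, w) or bwd.data.shape != (n, 2, h, w) \
            or mask.shape != (n, h, w):
        raise ValueError("shape mismatch between template, fields, data and mask")
    rep = tpl.reshape(1, 1, h, w) * np.ones((n, 1, 1, 1), dtype=tpl.data.dtype)
    warped = diffeo.warp_t(rep, bwd)          # (N, 1, H, W) real
    if phase is None:
        zeros = Tensor(np.zeros((n, 1, h, w), dtype=warped.data.dtype))
        lifted = ad.concatenate([warped, zeros], axis=1)
    else:
        phase = np.asarray(phase)
        lifted = ad.concatenate([warped * phase.real[:, None],
                                 warped * phase.imag[:, None]], axis=1)
    return ad.data_consistency_op(lifted, acquired, mask)


def dealias_step(net: DealiasingNetwork, G_prev, G_zero, X_prev) -> Tensor:
    """Residual dealiasing Z = H_phi(stack(G_prev, G_zero, X_prev)) + X_prev.

    All inputs are (N, 2, H, W) tensors; in motion_mode "none" the G inputs
    must be None and only X_prev is stacked.
    """
    cfg = net.config
    sources = []
    if cfg.motion_mode == "full":
        if G_prev is None:
            raise ValueError("motion_mode 'full' requires motion-augmented inputs")
        sources.append(G_prev)
        if cfg.use_zero_fill_branch:
            if G_zero is None:
                raise ValueError("zero-fill branch enabled but G_zero missing")
            sources.append(G_zero)
    elif G_prev is not None or G_zero is not None:
        raise ValueError("motion inputs supplied in motion_mode 'none'")
    sources.append(X_prev)
    # (N, 2, H, W) -> (2, N, H, W) per source, stacked along channels
    stacked = ad.concatenate([s.transpose(1, 0, 2, 3) for s in sources], axis=0)
    if stacked.data.shape[0] != cfg.in_channels:
        raise ValueError(f"expected {cfg.in_channels} channels, got "
                         f"{stacked.data.shape[0]}")
    resid = net.unet(stacked).transpose(1, 0, 2, 3)
    return resid + X_prev


@dataclass
class IterationState:
    """Artifacts of one unrolled iteration (all tensors; `.data` for numpy)."""

    k: int
    recon: Tensor                      # X^k, (N, 2, H, W)
    generated: Tensor | None           # G used at this iteration
    dealiased: Tensor                  # Z^k
    velocities: Tensor | None          # v^k (None in motion-free mode)
    forward: Tensor | None             # T^k displacements
    backward: Tensor | None            # T^k inverse displacements
    template: Tensor | None

    @property
    def recon_complex(self) -> np.ndarray:
        return channels_to_complex(self.recon)


def _register(reg_net, magnitudes_t, n_steps, phase_ref=None):
    """One GRN pass: velocities, deformations, registration target."""
    cfg = reg_net.config
    v = reg_net.predict(magnitudes_t)
    fwd, bwd = diffeo.integrate_both_t(v, n_steps)
    tpl = select_reference(cfg.mode, magnitudes_t, fwd,
                           cfg.reference_frame_index)
    return v, fwd, bwd, tpl


def unrolled_forward(reg_net: RegistrationNetwork | None,
                     recon_net: DealiasingNetwork,
                     under_kspace: KSpaceSequence,
                     mask: SamplingMask,
                     config: ReconConfig | None = None) -> list[IterationState]:
    """Run the K-iteration cascade from undersampled k-space.

    Returns one :class:`IterationState` per iteration; every reconstruction
    satisfies data consistency exactly on the mask support.  With
    zero-initialized networks the cascade is an identity map (X^K = X^0).
    """
    config = config or recon_net.config
    if under_kspace.spectra.shape != mask.masks.shape:
        raise ValueError("k-space and mask shapes differ")
    acq = np.asarray(under_kspace.spectra)
    m = np.asarray(mask.masks).astype(np.float64)
    n = acq.shape[0]

    x0c = np.fft.fftshift(np.fft.ifft2(
        np.fft.ifftshift(acq, axes=(-2, -1)), norm="ortho"), axes=(-2, -1))
    x0 = Tensor(complex_to_channels(x0c))

    use_motion = config.motion_mode == "full"
    if use_motion and reg_net is None:
        raise ValueError("motion_mode 'full' requires a registration network")
    n_steps = reg_net.config.integration_steps if reg_net is not None \
        else diffeo.DEFAULT_N_STEPS

    G0 = None
    reg0 = None
    if use_motion:
        mag0 = Tensor(np.abs(x0c).astype(np.float32))
        reg0 = _register(reg_net, mag0, n_steps)
        phase0 = _phase(config, x0c)
        G0 = motion_augment(reg0[3], reg0[2], acq, m, phase0)

    states: list[IterationState] = []
    x_prev = x0
    for k in range(1, config.iterations + 1):
        if use_motion:
            if k == 1:
                v, fwd, bwd, tpl = reg0
                G = G0
            else:
                magk = magnitude_t(x_prev)
                v, fwd, bwd, tpl = _register(reg_net, magk, n_steps)
                G = motion_augment(tpl, bwd, acq, m, _phase(config, x_prev))
            z = dealias_step(recon_net, G, G0 if config.use_zero_fill_branch
                             else None, x_prev)
        else:
            v = fwd = bwd = tpl = G = None
            z = dealias_step(recon_net, None, None, x_prev)
        xk = ad.data_consistency_op(z, acq, m)
        states.append(IterationState(k=k, recon=xk, generated=G, dealiased=z,
                                     velocities=v, forward=fwd, backward=bwd,
                                     template=tpl))
        x_prev = xk
    return states


def _phase(config: ReconConfig, x_prev):
    """Unit-modulus phase to lift the real template with (or None)."""
    if config.phase_source == "zero":
        return None
    xc = x_prev if isinstance(x_prev, np.ndarray) else channels_to_complex(x_prev)
    mag = np.abs(xc)
    return np.where(mag > 1e-12, xc / np.maximum(mag, 1e-12), 1.0 + 0j)
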