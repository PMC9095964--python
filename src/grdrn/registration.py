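"""Groupwise diffeomorphic registration network (GRN).

A 2D encoder-decoder takes the N magnitude frames stacked along the channel
axis and predicts N stationary velocity fields (2N output channels).  In
groupwise mode the fields are centered so they sum to zero, pinning the
implicit template — the average of the forward-warped frames — to the
geometric center of the group.  In the pairwise ablation the sequence is
registered to a designated reference frame instead and that frame's own
velocity field is forced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import diffeo, nn
from .autodiff import Tensor, as_tensor
from .containers import DeformationFieldSet

__all__ = ["RegistrationConfig", "RegistrationNetwork", "predict_velocities",
           "compute_template", "select_reference", "registration_loss",
           "DEFAULT_CHANNELS"]

DEFAULT_CHANNELS = (32, 64, 128, 256, 128, 64, 32)


@dataclass
class RegistrationConfig:
    n_frames: int
    channels: tuple = DEFAULT_CHANNELS
    leaky_slope: float = 0.01
    mode: str = "groupwise"
    reference_frame_index: int = 0
    integration_steps: int = diffeo.DEFAULT_N_STEPS
    zero_init_final_layer: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("groupwise", "pairwise"):
            raise ValueError("mode must be 'groupwise' or 'pairwise'")
        if not 0 <= self.reference_frame_index < self.n_frames:
            raise ValueError("reference_frame_index out of range")


class RegistrationNetwork:
    """Velocity-field predictor F_theta for a fixed frame count N."""

    def __init__(self, config: RegistrationConfig):
        self.config = config
        self.unet = nn.UNet(
            in_channels=config.n_frames,
            out_channels=2 * config.n_frames,
            channels=config.channels,
            ndim=2,
            leaky_slope=config.leaky_slope,
            zero_init_final=config.zero_init_final_layer,
            seed=config.seed,
        )

    def parameters(self):
        return self.unet.parameters()

    def predict(self, magnitudes) -> Tensor:
        """Predict velocity fields from N real magnitude frames.

        magnitudes: (N, H, W) ndarray or Tensor.  Returns a Tensor
        (N, 2, H, W); centered in groupwise mode, reference field zeroed in
        pairwise mode.
        """
        x = as_tensor(magnitudes)
        n = self.config.n_frames
        if x.data.shape[0] != n:
            raise ValueError(f"network configured for {n} frames, got "
                             f"{x.data.shape[0]}")
        h, w = x.data.shape[1:]
        raw = self.unet(x).reshape(n, 2, h, w)
        if self.config.mode == "groupwise":
            return raw - raw.mean(axis=0, keepdims=True)
        keep = np.ones((n, 1, 1, 1), dtype=raw.data.dtype)
        keep[self.config.reference_frame_index] = 0.0
        return raw * keep


def predict_velocities(net: RegistrationNetwork, magnitudes: np.ndarray) -> np.ndarray:
    """Numpy entry point for :meth:`RegistrationNetwork.predict`."""
    return net.predict(np.asarray(magnitudes, dtype=np.float32)).data


# ---------------------------------------------------------------------------
# implicit template and registration loss (tensor-generic)
# ---------------------------------------------------------------------------

def _wrap(x, dtype=np.float64):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=dtype))


def compute_template(frames, forward):
    """Implicit template: the average of the forward-warped frames.

    frames: (N, H, W) magnitudes; forward: (N, 2, H, W) displacements.
    Returns the (H, W) template (ndarray in, ndarray out; Tensor in,
    Tensor out).
    """
    tensor_in = isinstance(frames, Tensor) or isinstance(forward, Tensor)
    f, d = _wrap(frames), _wrap(forward)
    if f.data.shape[0] != d.data.shape[0] or f.data.shape[-2:] != d.data.shape[-2:]:
        raise ValueError("frames and forward fields do not match")
    warped = diffeo.warp_t(f.reshape(f.data.shape[0], 1, *f.data.shape[1:]), d)
    tpl = warped.mean(axis=0)[0]
    return tpl if tensor_in else tpl.data


def select_reference(mode, frames, forward, reference_frame_index=0):
    """Registration target: implicit template (groupwise) or a designated,
    unwarped frame (pairwise)."""
    if mode == "groupwise":
        return compute_template(frames, forward)
    if mode == "pairwise":
        n = frames.data.shape[0] if isinstance(frames, Tensor) else frames.shape[0]
        if not 0 <= reference_frame_index < n:
            raise ValueError("reference_frame_index out of range")
        return frames[reference_frame_index]
    raise ValueError("mode must be 'groupwise' or 'pairwise'")


def registration_loss(gt_magnitudes, deformations, velocities, alpha,
                      mode="groupwise", reference_frame_index=0):
    """Similarity + smoothness loss of a registration.

    ``(1/N) sum ||ref - T_n o X_n||^2 + (1/N) sum ||X_n - T_n^-1 o ref||^2
    + alpha * smoothness(v)`` with mean-per-pixel squared norms, where the
    reference is recomputed from the supplied frames and forward fields
    (implicit template in groupwise mode, the designated frame in pairwise
    mode).

    Accepts ndarrays (returns float) or Tensors (returns a scalar Tensor
    for training).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    tensor_in = any(isinstance(t, Tensor)
                    for t in (gt_magnitudes, velocities))
    x = _wrap(gt_magnitudes)
    v = _wrap(velocities)
    if isinstance(deformations, DeformationFieldSet):
        fwd, bwd = _wrap(deformations.forward), _wrap(deformations.backward)
    else:
        fwd, bwd = _wrap(deformations[0]), _wrap(deformations[1])
    n, h, w = x.data.shape
    ref = select_reference(mode, x, fwd, reference_frame_index)
    x4 = x.reshape(n, 1, h, w)
    warped_fwd = diffeo.warp_t(x4, fwd)[:, 0]
    term1 = (ref.reshape(1, h, w) - warped_fwd).square().mean()
    ref_rep = ref.reshape(1, 1, h, w) * np.ones((n, 1, 1, 1),
                                                dtype=ref.data.dtype)
    regen = diffeo.warp_t(ref_rep, bwd)[:, 0]
    term2 = (x - regen).square().mean()
    loss = term1 + term2 + alpha * diffeo.smoothness_t(v)
    return loss if tensor_in else float(loss.data)
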