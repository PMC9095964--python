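"""Stationary-velocity-field diffeomorphic machinery.

A stationary velocity field v is integrated over unit time by scaling and
squaring to produce an invertible displacement field; integrating -v gives
its inverse.  Fields are stored in pixels, component order (row, col), as
(..., 2, H, W) arrays.  Warping is backward-mapping bilinear resampling with
border replication and is differentiable in both arguments, so the same
code path serves plain numpy callers and network training.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .containers import DeformationFieldSet

__all__ = ["center_velocities", "integrate_velocity", "invert_by_negation",
           "warp_image", "smoothness_penalty", "compose_displacements",
           "DEFAULT_N_STEPS"]

DEFAULT_N_STEPS = 7


# ---------------------------------------------------------------------------
# tensor-native core (shapes: fields (N, 2, H, W), images (N, C, H, W))
# ---------------------------------------------------------------------------

def warp_t(image: Tensor, disp: Tensor) -> Tensor:
    """Differentiable warp; image (N, C, H, W), disp (N, 2, H, W)."""
    return ad.warp(image, disp)


def compose_t(d_outer: Tensor, d_inner: Tensor) -> Tensor:
    """Displacement of applying d_inner then d_outer: d_inner + d_outer(x + d_inner)."""
    return d_inner + ad.warp(d_outer, d_inner)


def _central_diff(t: Tensor, axis: int) -> Tensor:
    """Same-shape spatial derivative: central interior, one-sided borders."""
    n = t.data.shape[axis]
    sl = [slice(None)] * t.data.ndim

    def take(a, b):
        sl2 = list(sl)
        sl2[axis] = slice(a, b)
        return t[tuple(sl2)]

    inner = (take(2, n) - take(0, n - 2)) * 0.5
    first = take(1, 2) - take(0, 1)
    last = take(n - 1, n) - take(n - 2, n - 1)
    return ad.concatenate([first, inner, last], axis=axis)


def integrate_t(v: Tensor, n_steps: int = DEFAULT_N_STEPS) -> Tensor:
    """Unit-time flow of stationary fields v (N, 2, H, W) by scaling-squaring.

    The initial small-time step uses the second-order Taylor expansion of
    the flow, phi_0 = h v + (h^2/2) (Dv) v with h = 2^-n_steps, which
    removes the dominant first-order error of the plain phi_0 = h v
    initialization; the recursive compositions then square phi_0 up to
    unit time.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    h = float(2.0 ** -n_steps)
    dvr = _central_diff(v, 2)
    dvc = _central_diff(v, 3)
    vr, vc = v[:, 0:1], v[:, 1:2]
    adv_r = dvr[:, 0:1] * vr + dvc[:, 0:1] * vc
    adv_c = dvr[:, 1:2] * vr + dvc[:, 1:2] * vc
    adv = ad.concatenate([adv_r, adv_c], axis=1)
    phi = v * h + adv * (0.5 * h * h)
    for _ in range(n_steps):
        phi = compose_t(phi, phi)
    return phi


def integrate_both_t(v: Tensor, n_steps: int = DEFAULT_N_STEPS):
    """Integrate +v and -v in one batched pass; returns (forward, backward)."""
    n = v.data.shape[0]
    both = ad.concatenate([v, v * (-1.0)], axis=0)
    phi = integrate_t(both, n_steps)
    return phi[:n], phi[n:]


def smoothness_t(v: Tensor) -> Tensor:
    """Mean over frames of the squared forward-difference gradient energy.

    Per frame: spatial mean of the squared row- and column-differences,
    summed over the two field components and the two difference directions.
    A single linear ramp of slope s therefore scores s^2.
    """
    dr = v[:, :, 1:, :] - v[:, :, :-1, :]
    dc = v[:, :, :, 1:] - v[:, :, :, :-1]
    n = v.data.shape[0]
    per_frame = dr.square().mean(axis=(2, 3)).sum(axis=1) \
        + dc.square().mean(axis=(2, 3)).sum(axis=1)
    return per_frame.sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# numpy-facing API
# ---------------------------------------------------------------------------

def _check_finite(v):
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity field contains non-finite values")


def center_velocities(v: np.ndarray) -> np.ndarray:
    """Subtract the across-frame mean field so the fields sum to zero.

    This pins the implicit template to the geometric center of the group.
    v: (N, 2, H, W).
    """
    v = np.asarray(v)
    return v - v.mean(axis=0, keepdims=True)


def integrate_velocity(v: np.ndarray, n_steps: int = DEFAULT_N_STEPS) -> np.ndarray:
    """Integrate one field (2, H, W) or a set (N, 2, H, W) over unit time."""
    v = np.asarray(v, dtype=np.float64)
    _check_finite(v)
    single = v.ndim == 3
    if single:
        v = v[None]
    out = integrate_t(Tensor(v), n_steps).data
    return out[0] if single else out


def invert_by_negation(v: np.ndarray,
                       n_steps: int = DEFAULT_N_STEPS) -> DeformationFieldSet:
    """Forward transforms from +v and their inverses from -v."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 4 or v.shape[1] != 2:
        raise ValueError("expected velocity set of shape (N, 2, H, W)")
    _check_finite(v)
    fwd, bwd = integrate_both_t(Tensor(v), n_steps)
    return DeformationFieldSet(forward=fwd.data, backward=bwd.data)


def warp_image(image: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Resample image(s) at x + displacement(x) (bilinear, border replication).

    image: (H, W) or (N, H, W), real or complex; displacement: matching
    (2, H, W) or (N, 2, H, W).
    """
    image = np.asarray(image)
    displacement = np.asarray(displacement, dtype=np.float64)
    single = image.ndim == 2
    if single:
        image, displacement = image[None], displacement[None]
    if image.shape[-2:] != displacement.shape[-2:] or \
            displacement.shape[-3] != 2 or image.shape[0] != displacement.shape[0]:
        raise ValueError("image and displacement shapes do not match")
    if np.iscomplexobj(image):
        stack = np.stack([image.real, image.imag], axis=1)
        w = ad.warp(Tensor(stack), Tensor(displacement)).data
        out = w[:, 0] + 1j * w[:, 1]
    else:
        out = ad.warp(Tensor(image[:, None].astype(np.float64)),
                      Tensor(displacement)).data[:, 0]
    return out[0] if single else out


def compose_displacements(d_outer: np.ndarray, d_inner: np.ndarray) -> np.ndarray:
    """Displacement of the composition 'apply d_inner, then d_outer'."""
    d_outer = np.asarray(d_outer, dtype=np.float64)
    d_inner = np.asarray(d_inner, dtype=np.float64)
    single = d_outer.ndim == 3
    if single:
        d_outer, d_inner = d_outer[None], d_inner[None]
    out = compose_t(Tensor(d_outer), Tensor(d_inner)).data
    return out[0] if single else out


def smoothness_penalty(v: np.ndarray) -> float:
    """Mean squared forward-difference gradient of a velocity set (N, 2, H, W)."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 3:
        v = v[None]
    return float(smoothness_t(Tensor(v)).data)
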