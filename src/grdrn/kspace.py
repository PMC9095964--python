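"""MRI acquisition model: centered orthonormal Fourier operators,
Gaussian-density Cartesian undersampling, zero-filled reconstruction and
data-consistency enforcement.

Undersampling skips phase-encode lines (columns); each kept line is fully
read along the frequency-encode axis (rows).  The sampling density follows
a zero-mean Gaussian over the line offset from the k-space center and the
five central lines are always acquired.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import DynamicSequence, KSpaceSequence, SamplingMask

__all__ = [
    "forward_fft", "inverse_fft", "generate_mask", "undersample",
    "zero_fill_recon", "data_consistency", "sequence_to_kspace",
    "central_line_indices",
]

N_CENTRAL_LINES = 5
SUPPORTED_ACCELERATIONS = (8, 12, 16)


def forward_fft(frame: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D DFT of one frame (or a stack of frames).

    The DC component sits at the array center; ``inverse_fft`` is the exact
    inverse and the pair conserves energy (Parseval).
    """
    frame = np.asarray(frame)
    if frame.ndim < 2:
        raise ValueError("expected a 2D frame (or stack of 2D frames)")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(frame, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def inverse_fft(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_fft`."""
    spectrum = np.asarray(spectrum)
    if spectrum.ndim < 2:
        raise ValueError("expected a 2D spectrum (or stack)")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(spectrum, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def central_line_indices(n_pe: int) -> np.ndarray:
    """Indices of the 5 central phase-encode lines (center = n_pe // 2)."""
    c = n_pe // 2
    return np.arange(c - 2, c + 3)


def generate_mask(n_pe: int, n_fe: int, n_frames: int, acceleration: float,
                  rng_seed: int, sigma: float | None = None,
                  shared_across_frames: bool = False) -> SamplingMask:
    """Draw per-frame Cartesian undersampling masks.

    Per frame, ``round(n_pe / acceleration)`` distinct phase-encode lines
    are sampled without replacement with probability proportional to a
    zero-mean Gaussian over the offset from the center line, and the 5
    central lines are always included.  Masks are independent across frames
    unless ``shared_across_frames`` is set.

    Parameters
    ----------
    n_pe, n_fe : int
        Phase-encode (columns) and frequency-encode (rows) sizes.
    acceleration : float
        Target acceleration factor R >= 1.
    rng_seed : int
        Seed for the mask stream (reproducible).
    sigma : float, optional
        Std of the Gaussian line density; defaults to ``n_pe / 6`` so the
        line range spans +-3 sigma.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    if n_pe < N_CENTRAL_LINES:
        raise ValueError(f"n_pe must be >= {N_CENTRAL_LINES}")
    if sigma is None:
        sigma = n_pe / 6.0
    n_lines = int(round(n_pe / acceleration))
    if n_lines < N_CENTRAL_LINES:
        warnings.warn(
            f"round(n_pe/acceleration) = {n_lines} < {N_CENTRAL_LINES}; "
            "sampling only the central lines", stacklevel=2)
        n_lines = N_CENTRAL_LINES
    n_lines = min(n_lines, n_pe)

    rng = np.random.default_rng(rng_seed)
    center = n_pe // 2
    central = central_line_indices(n_pe)
    others = np.setdiff1d(np.arange(n_pe), central)
    weights = np.exp(-0.5 * ((others - center) / sigma) ** 2)
    weights /= weights.sum()

    masks = np.zeros((n_frames, n_fe, n_pe), dtype=np.uint8)
    n_extra = n_lines - N_CENTRAL_LINES
    chosen = None
    for t in range(n_frames):
        if chosen is None or not shared_across_frames:
            extra = rng.choice(others, size=n_extra, replace=False, p=weights) \
                if n_extra > 0 else np.empty(0, dtype=int)
            chosen = np.concatenate([central, extra.astype(int)])
        masks[t, :, chosen] = 1
    return SamplingMask(masks=masks, acceleration=float(acceleration))


def sequence_to_kspace(seq: DynamicSequence) -> KSpaceSequence:
    """Forward-transform every frame of a sequence."""
    return KSpaceSequence(spectra=forward_fft(seq.frames), is_undersampled=False)


def undersample(full_kspace: KSpaceSequence, mask: SamplingMask) -> KSpaceSequence:
    """Apply binary masks to fully sampled spectra."""
    if full_kspace.spectra.shape != mask.masks.shape:
        raise ValueError("k-space and mask shapes differ")
    return KSpaceSequence(spectra=full_kspace.spectra * mask.masks,
                          is_undersampled=True)


def zero_fill_recon(under_kspace: KSpaceSequence) -> DynamicSequence:
    """Per-frame inverse FFT of (possibly undersampled) spectra."""
    return DynamicSequence(frames=inverse_fft(under_kspace.spectra))


def data_consistency(image: np.ndarray, acquired: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Enforce agreement with acquired k-space data.

    Returns ``inverse_fft(mask * acquired + (1 - mask) * forward_fft(image))``:
    sampled coefficients are replaced by the measurements, unsampled ones
    keep the candidate image's spectrum.  Idempotent; a fixed point for any
    image already consistent with the data.
    """
    image = np.asarray(image)
    acquired = np.asarray(acquired)
    mask = np.asarray(mask)
    if image.shape != acquired.shape or image.shape != mask.shape:
        raise ValueError("image, acquired and mask shapes must agree")
    k = forward_fft(image)
    return inverse_fft(mask * acquired + (1 - mask) * k)
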